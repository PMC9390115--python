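"""Parameter estimation from cultivation-trial observations.

Fits the logistic growth curve to plant-level fresh-weight records
(per site and pooled), the content sigmoid to chemical-assay records,
and an exponential baseline for model comparison; also estimates
moisture fractions from paired fresh/oven-dry weights.

Observations arrive as tidy DataFrames:

* biomass: columns ``site, dap, replicate, fresh_weight_g, dry_weight_g``
  (dry weight optional), weights in g plant⁻¹;
* chemistry: columns ``site, dap, fraction`` with fraction in
  kg chemical kg⁻¹ SDW.

The planting weight is treated as known (plants are weighed at
planting), so the growth fit has two free parameters, ``rgr_max`` and
``w_f_max``.  Default fit windows: growth on 7–63 days after planting
(biomass decline beyond day 63 is outside the model), chemistry on
0–49 days.  Standard errors come from the Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import linregress

from .growth import GrowthParams, biomass_at
from .postharvest import ChemicalParams, chemical_fraction

__all__ = [
    "FitResult",
    "GROWTH_WINDOW",
    "CHEM_WINDOW",
    "fit_logistic",
    "fit_chemical",
    "fit_exponential",
    "estimate_moisture",
    "per_site_fit",
    "fit_rgr_vs_covariate",
]

#: Default days-after-planting window for growth fits.
GROWTH_WINDOW = (7.0, 63.0)
#: Default days-after-planting window for chemical-content fits.
CHEM_WINDOW = (0.0, 49.0)

BIOMASS_COLUMNS = ["site", "dap", "replicate", "fresh_weight_g", "dry_weight_g"]
CHEM_COLUMNS = ["site", "dap", "fraction"]


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit."""

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    n_obs: int
    fit_window: tuple[float, float]
    converged: bool
    rss: float
    r_squared: float | None = None
    message: str = ""
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "n_obs": self.n_obs,
            "fit_window": list(self.fit_window),
            "converged": self.converged,
            "rss": self.rss,
            "r_squared": self.r_squared,
            "message": self.message,
        }


def _window_mask(dap: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (dap >= lo) & (dap <= hi)


def _standard_errors(res, names: list[str]) -> dict[str, float]:
    """SEs from the Jacobian at the optimum: sqrt(diag(s² (JᵀJ)⁻¹))."""
    n, p = res.jac.shape
    rss = float(2 * res.cost)
    if n <= p:
        return {k: float("nan") for k in names}
    s2 = rss / (n - p)
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(names), np.nan)
    return dict(zip(names, map(float, se)))


def _failed_fit(names, n_obs, window, message) -> FitResult:
    return FitResult(
        estimates={k: float("nan") for k in names},
        standard_errors={k: float("nan") for k in names},
        n_obs=n_obs,
        fit_window=tuple(window),
        converged=False,
        rss=float("nan"),
        message=message,
    )


def _prepare_growth_data(
    obs: pd.DataFrame,
    window: tuple[float, float],
    use_date_means: bool,
) -> tuple[np.ndarray, np.ndarray]:
    dap = obs["dap"].to_numpy(dtype=float)
    w = obs["fresh_weight_g"].to_numpy(dtype=float)
    m = _window_mask(dap, window) & np.isfinite(w)
    dap, w = dap[m], w[m]
    if use_date_means:
        means = pd.DataFrame({"dap": dap, "w": w}).groupby("dap")["w"].mean()
        dap, w = means.index.to_numpy(), means.to_numpy()
    return dap, w


def _initial_rgr(dap: np.ndarray, w: np.ndarray) -> float:
    """Log-linear slope of the early-window weights (the growth curve is
    exponential at low biomass, so log w is linear in t there)."""
    early = dap <= np.quantile(dap, 0.5)
    if early.sum() >= 2 and np.all(w[early] > 0):
        slope = linregress(dap[early], np.log(w[early])).slope
        if np.isfinite(slope) and slope > 0:
            return min(float(slope), 1.0)
    return 0.05


def fit_logistic(
    obs: pd.DataFrame,
    w_f0: float,
    window: tuple[float, float] = GROWTH_WINDOW,
    use_date_means: bool = False,
) -> FitResult:
    """Fit the logistic growth curve to fresh-weight observations.

    The planting weight ``w_f0`` (g plant⁻¹) is fixed; ``rgr_max``
    (day⁻¹) and ``w_f_max`` (g plant⁻¹) are estimated by least squares
    on the plant-level replicates inside the window (or on per-date
    means when ``use_date_means``).  Non-convergence yields a
    ``FitResult`` with ``converged=False``, never an exception.
    """
    names = ["rgr_max", "w_f_max"]
    if w_f0 <= 0:
        raise ValueError(f"w_f0 must be > 0, got {w_f0}")
    dap, w = _prepare_growth_data(obs, window, use_date_means)
    if np.unique(dap).size < 3:
        return _failed_fit(names, w.size, window, "need >= 3 distinct dap values")

    wmax_obs = float(w.max())
    x0 = np.array([_initial_rgr(dap, w), 1.2 * wmax_obs])
    lb = np.array([1e-8, max(0.5 * wmax_obs, w_f0 * (1 + 1e-9))])
    ub = np.array([1.0, 10.0 * wmax_obs])
    x0 = np.clip(x0, lb, ub)

    def resid(theta):
        rgr, wmax = theta
        return biomass_at(dap, w_f0, GrowthParams(rgr, wmax)) - w

    try:
        res = optimize.least_squares(
            resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
    except Exception as exc:  # pragma: no cover - defensive
        return _failed_fit(names, w.size, window, str(exc))
    at_bound = bool(np.any(np.isclose(res.x, lb)) or np.any(np.isclose(res.x, ub)))
    fit = FitResult(
        estimates=dict(zip(names, map(float, res.x))),
        standard_errors=_standard_errors(res, names),
        n_obs=int(w.size),
        fit_window=tuple(window),
        converged=bool(res.success) and not at_bound,
        rss=float(2 * res.cost),
        message=res.message if not res.success else ("at bound" if at_bound else ""),
    )
    fit.extras["w_f_max_g_plant"] = fit.estimates["w_f_max"]
    return fit


def fit_chemical(
    obs: pd.DataFrame,
    window: tuple[float, float] = CHEM_WINDOW,
) -> FitResult:
    """Fit the four-parameter content sigmoid to chemical-assay records.

    Estimates ``cf_min, cf_max, cfk, cft50`` by least squares within the
    window and reports R² of the fitted curve against the observations.
    """
    names = ["cf_min", "cf_max", "cfk", "cft50"]
    dap = obs["dap"].to_numpy(dtype=float)
    y = obs["fraction"].to_numpy(dtype=float)
    m = _window_mask(dap, window) & np.isfinite(y)
    dap, y = dap[m], y[m]
    if np.unique(dap).size < 4:
        return _failed_fit(names, y.size, window, "need >= 4 distinct dap values")

    x0 = np.array([float(y.min()), float(y.max()), 0.1, float(np.median(dap))])
    lb = np.array([0.0, 0.0, 1e-6, 1e-6])
    ub = np.array([1.0, 1.0, 2.0, 10.0 * dap.max()])
    x0 = np.clip(x0, lb + 1e-9, ub)

    def resid(theta):
        cmin, cmax, k, t50 = theta
        return cmin + (cmax - cmin) / (1.0 + np.exp(-k * (dap - t50))) - y

    try:
        res = optimize.least_squares(
            resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
    except Exception as exc:  # pragma: no cover - defensive
        return _failed_fit(names, y.size, window, str(exc))
    rss = float(2 * res.cost)
    tss = float(np.sum((y - y.mean()) ** 2))
    return FitResult(
        estimates=dict(zip(names, map(float, res.x))),
        standard_errors=_standard_errors(res, names),
        n_obs=int(y.size),
        fit_window=tuple(window),
        converged=bool(res.success),
        rss=rss,
        r_squared=1.0 - rss / tss if tss > 0 else None,
        message="" if res.success else res.message,
    )


def fit_exponential(
    obs: pd.DataFrame,
    window: tuple[float, float] = GROWTH_WINDOW,
    use_date_means: bool = False,
) -> FitResult:
    """Fit the exponential baseline ``w(t) = w_f0 · e^(rgr·t)``.

    Both the rate and the intercept are free.  Serves as the classical
    model against which the logistic fit is compared (on the same
    window, via rss); on sigmoid data restricted to the early phase its
    rate approaches the logistic ``rgr_max``.
    """
    names = ["rgr", "w_f0_hat"]
    dap, w = _prepare_growth_data(obs, window, use_date_means)
    if np.unique(dap).size < 3:
        return _failed_fit(names, w.size, window, "need >= 3 distinct dap values")

    x0 = np.array([_initial_rgr(dap, w), max(float(w.min()), 1e-6)])

    def resid(theta):
        rgr, w0 = theta
        return w0 * np.exp(rgr * dap) - w

    try:
        res = optimize.least_squares(
            resid, x0, bounds=([0.0, 1e-12], [2.0, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except Exception as exc:  # pragma: no cover - defensive
        return _failed_fit(names, w.size, window, str(exc))
    return FitResult(
        estimates=dict(zip(names, map(float, res.x))),
        standard_errors=_standard_errors(res, names),
        n_obs=int(w.size),
        fit_window=tuple(window),
        converged=bool(res.success),
        rss=float(2 * res.cost),
        message="" if res.success else res.message,
    )


def estimate_moisture(fresh: np.ndarray, dry: np.ndarray) -> float:
    """Mean moisture fraction from paired fresh and oven-dry weights.

    Per sample, moisture = 1 − dry/fresh; the estimate is the mean over
    samples.
    """
    fresh = np.asarray(fresh, dtype=float)
    dry = np.asarray(dry, dtype=float)
    if np.any(fresh <= 0):
        raise ValueError("fresh weights must be > 0")
    if np.any(dry < 0) or np.any(dry > fresh):
        raise ValueError("dry weights must lie in [0, fresh]")
    return float(np.mean(1.0 - dry / fresh))


def per_site_fit(
    obs: pd.DataFrame,
    w_f0: float,
    window: tuple[float, float] = GROWTH_WINDOW,
    use_date_means: bool = False,
) -> dict[str, FitResult]:
    """Logistic fit per site plus a pooled fit over all sites.

    Returns a mapping site label → FitResult, with the pooled fit under
    the key ``"pooled"``.  Sites whose fit fails to converge are flagged
    in their FitResult, not dropped.
    """
    out: dict[str, FitResult] = {}
    for site, group in obs.groupby("site", sort=True):
        out[str(site)] = fit_logistic(group, w_f0, window, use_date_means)
    out["pooled"] = fit_logistic(obs, w_f0, window, use_date_means)
    return out


def fit_rgr_vs_covariate(
    site_fits: dict[str, FitResult],
    covariate: dict[str, float],
) -> dict[str, float]:
    """Ordinary least squares of per-site ``rgr_max`` on a site covariate.

    A descriptive helper (e.g. growth rate vs distance from a river
    mouth): reports slope, intercept and their standard errors, with no
    significance verdict and no support for extrapolation.
    """
    sites = [s for s in site_fits if s != "pooled" and s in covariate]
    if len(sites) < 3:
        raise ValueError("need >= 3 sites with covariate values")
    x = np.array([covariate[s] for s in sites], dtype=float)
    y = np.array([site_fits[s].estimates["rgr_max"] for s in sites])
    reg = linregress(x, y)
    return {
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "slope_se": float(reg.stderr),
        "intercept_se": float(reg.intercept_stderr),
        "n_sites": len(sites),
    }
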