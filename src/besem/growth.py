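"""Logistic (Verhulst) growth with multi-cycle harvest scheduling.

The biomass of a farmed seaweed line, expressed as fresh weight per unit
sea area (kg FW m⁻²), follows the logistic growth equation

    dw/dt = RGR_max · w · (1 − w / w_f_max)

whose closed-form solution from a replanting weight ``w_f0`` is the
sigmoid evaluated by :func:`biomass_at`.  A farm runs repeated harvest
cycles of ``hcl`` days (the harvest/replant day included); within a
360-day farming year this produces a sawtooth biomass trajectory that
resets to ``w_f0`` at each harvest.  :func:`annual_net_fresh` aggregates
the per-cycle net harvest (gross at harvest minus the replanted weight)
over the ``360/hcl`` cycles of the year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthParams",
    "ManagementPlan",
    "AnnualYield",
    "logistic_rate",
    "biomass_at",
    "cycle_day",
    "harvests_per_year",
    "growing_period",
    "annual_net_fresh",
    "sawtooth_series",
]

#: Length of the farming year in days; harvest counts are annualised
#: against this, so 360/hcl is a real number for cycle lengths that do
#: not divide it evenly.
YEAR_DAYS = 360


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth parameters.

    Attributes
    ----------
    rgr_max : float
        Maximum relative growth rate (day⁻¹), attained at low biomass.
    w_f_max : float
        Maximum attainable gross fresh biomass density, the carrying
        capacity of the logistic curve (kg FW m⁻²).
    """

    rgr_max: float
    w_f_max: float

    def __post_init__(self) -> None:
        if not self.rgr_max > 0:
            raise ValueError(f"rgr_max must be > 0, got {self.rgr_max}")
        if not self.w_f_max > 0:
            raise ValueError(f"w_f_max must be > 0, got {self.w_f_max}")


@dataclass(frozen=True)
class ManagementPlan:
    """Farmer decisions: cycle length, replanting weight, planting day.

    Attributes
    ----------
    hcl : int
        Harvest cycle length in whole days, counted to include the
        harvest day; the in-sea growing period is ``hcl − 1`` days.
        ``hcl = 1`` is rejected: it leaves no growing day, so net yield
        is identically zero.
    w_f0 : float
        Replanting weight (kg FW m⁻²), the part of each harvest
        re-attached to the lines to seed the next cycle.
    doy0 : int
        Planting day of year (1–360).
    """

    hcl: int
    w_f0: float
    doy0: int = 1

    def __post_init__(self) -> None:
        if int(self.hcl) != self.hcl or self.hcl < 2:
            raise ValueError(f"hcl must be an integer >= 2, got {self.hcl}")
        if not self.w_f0 > 0:
            raise ValueError(f"w_f0 must be > 0, got {self.w_f0}")
        if not 1 <= self.doy0 <= YEAR_DAYS:
            raise ValueError(f"doy0 must be in [1, {YEAR_DAYS}], got {self.doy0}")

    def validate_against(self, params: GrowthParams) -> None:
        """Check the cross-invariant w_f0 < w_f_max."""
        if not self.w_f0 < params.w_f_max:
            raise ValueError(
                f"replanting weight w_f0={self.w_f0} must be below "
                f"w_f_max={params.w_f_max}"
            )


@dataclass(frozen=True)
class AnnualYield:
    """Per-cycle and annualised fresh-yield accounting for one plan."""

    n_h: float  # harvests per year (real-valued, 360/hcl)
    gross_per_cycle: float  # kg FW m⁻² at harvest
    net_per_cycle: float  # gross minus replanted weight
    annual_net_fresh: float  # kg FW m⁻² year⁻¹
    fraction_sold: float  # net/gross, dimensionless


def logistic_rate(w, params: GrowthParams):
    """Instantaneous biomass growth rate dw/dt (kg FW m⁻² day⁻¹).

    Zero at ``w = 0`` and at the carrying capacity ``w = w_f_max``,
    maximal (``rgr_max·w_f_max/4``) at half the carrying capacity.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > params.w_f_max):
        raise ValueError("biomass w must lie in [0, w_f_max]")
    return params.rgr_max * w * (1.0 - w / params.w_f_max)


def biomass_at(t, w_f0: float, params: GrowthParams):
    """Gross fresh biomass (kg FW m⁻²) at ``t`` days after planting.

    Closed-form logistic solution

        w(t) = w_f_max / (1 + ((w_f_max − w_f0)/w_f0) · e^(−rgr_max·t))

    with ``w(0) = w_f0``, strictly increasing in ``t`` and bounded above
    by ``w_f_max``.  Accepts scalar or array ``t``.
    """
    if not 0 < w_f0 < params.w_f_max:
        raise ValueError(
            f"w_f0 must lie strictly between 0 and w_f_max={params.w_f_max}, "
            f"got {w_f0}"
        )
    t = np.asarray(t, dtype=float)
    a = (params.w_f_max - w_f0) / w_f0
    out = params.w_f_max / (1.0 + a * np.exp(-params.rgr_max * t))
    return out if out.ndim else float(out)


def cycle_day(doy, doy0: int, hcl: int):
    """Days after planting for a day of year under a repeating cycle.

    Mathematical modulo ``mod(doy − doy0, hcl)``: the result lies in
    ``[0, hcl − 1]`` even when ``doy < doy0``, producing a sawtooth that
    resets to 0 on each harvest/replant day.
    """
    if hcl < 1:
        raise ValueError(f"hcl must be >= 1, got {hcl}")
    doy = np.asarray(doy)
    out = np.mod(doy - doy0, hcl)
    return out if out.ndim else int(out)


def harvests_per_year(hcl: int) -> float:
    """Number of harvest cycles per 360-day year, ``360/hcl``, real-valued."""
    if hcl < 1:
        raise ValueError(f"hcl must be >= 1, got {hcl}")
    return YEAR_DAYS / hcl


def growing_period(hcl: int) -> int:
    """In-sea growing days per cycle: one day per cycle is lost on land
    to harvesting, sorting and replanting, so ``lgp = hcl − 1``."""
    if hcl < 1:
        raise ValueError(f"hcl must be >= 1, got {hcl}")
    return hcl - 1


def annual_net_fresh(plan: ManagementPlan, params: GrowthParams) -> AnnualYield:
    """Annual net fresh yield for a management plan.

    The gross harvest of one cycle is the biomass after ``hcl − 1``
    growing days; the net (sold) harvest subtracts the replanted weight;
    the year holds ``360/hcl`` identical cycles.
    """
    plan.validate_against(params)
    gross = float(biomass_at(growing_period(plan.hcl), plan.w_f0, params))
    net = gross - plan.w_f0
    n_h = harvests_per_year(plan.hcl)
    return AnnualYield(
        n_h=n_h,
        gross_per_cycle=gross,
        net_per_cycle=net,
        annual_net_fresh=n_h * net,
        fraction_sold=net / gross,
    )


def sawtooth_series(
    plan: ManagementPlan,
    params: GrowthParams,
    doy_range: tuple[int, int] = (1, YEAR_DAYS),
):
    """Daily biomass trajectory over a span of the farming year.

    Returns a structured array of (doy, dap, biomass) where ``dap`` is
    the sawtooth days-after-planting and biomass re-evaluates the
    logistic curve at that ``dap`` — the series resets to ``w_f0`` on
    every harvest/replant day.
    """
    first, last = doy_range
    if last < first:
        raise ValueError(f"inverted doy range {doy_range}")
    if first < 1 or last > YEAR_DAYS:
        raise ValueError(f"doy range must lie within [1, {YEAR_DAYS}]")
    plan.validate_against(params)
    doy = np.arange(first, last + 1)
    dap = cycle_day(doy, plan.doy0, plan.hcl)
    biomass = biomass_at(dap, plan.w_f0, params)
    out = np.empty(
        doy.size,
        dtype=[("doy", int), ("dap", int), ("biomass", float)],
    )
    out["doy"], out["dap"], out["biomass"] = doy, dap, biomass
    return out
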