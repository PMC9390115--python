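"""Curve fitting and parameter recovery from trial observations."""

import numpy as np
import pandas as pd
import pytest

from besem import (
    ChemicalParams,
    FarmGeometry,
    GrowthParams,
    biomass_at,
    chemical_fraction,
    estimate_moisture,
    fit_chemical,
    fit_exponential,
    fit_logistic,
    per_plant_to_per_area,
    per_site_fit,
)
from besem.calibration import fit_rgr_vs_covariate
from besem.synthetic_data import (
    Decline,
    TrialDesign,
    default_trial_design,
    generate_trial,
)

W0_G = 10.86
TRUE_G = GrowthParams(rgr_max=0.0778, w_f_max=142.667)
SCHEDULE = (7, 14, 21, 28, 35, 42, 49, 63)


def noiseless_biomass(params=TRUE_G, schedule=SCHEDULE, w0=W0_G):
    rows = [
        {"site": "A", "dap": d, "replicate": r, "fresh_weight_g":
         float(biomass_at(d, w0, params)), "dry_weight_g": np.nan}
        for d in schedule
        for r in range(1, 6)
    ]
    return pd.DataFrame(rows)


def noiseless_chem(chem, schedule=(21, 28, 35, 42, 49)):
    return pd.DataFrame(
        [{"site": "A", "dap": d, "fraction": float(chemical_fraction(d, chem))}
         for d in schedule]
    )


class TestFitLogistic:
    def test_zero_noise_exact_recovery(self):
        fit = fit_logistic(noiseless_biomass(), W0_G)
        assert fit.converged
        assert fit.estimates["rgr_max"] == pytest.approx(0.0778, rel=1e-6)
        assert fit.estimates["w_f_max"] == pytest.approx(142.667, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_per_area_conversion_of_estimate(self):
        geom = FarmGeometry(l_n=600, l_l=25, l_w=0.75, l_pd=5)
        fit = fit_logistic(noiseless_biomass(), W0_G)
        per_m2 = per_plant_to_per_area(fit.estimates["w_f_max"], geom)
        assert per_m2 == pytest.approx(0.951113, rel=1e-5)

    def test_window_discipline(self):
        """Observations outside the fit window never affect estimates."""
        obs = noiseless_biomass(schedule=(7, 14, 21, 28, 35, 42, 49, 63, 77, 91))
        corrupted = obs.copy()
        out = corrupted["dap"] > 63
        corrupted.loc[out, "fresh_weight_g"] *= 0.2  # fake a biomass crash
        a = fit_logistic(obs, W0_G, window=(7, 63))
        b = fit_logistic(corrupted, W0_G, window=(7, 63))
        assert a.estimates == b.estimates

    def test_noisy_recovery_is_unbiased_as_noise_shrinks(self):
        biases = []
        for cv in (0.4, 0.1, 0.01):
            design = default_trial_design(seed=7, heterogeneous_sites=False)
            design.noise_cv = cv
            obs, _ = generate_trial(design)
            fit = fit_logistic(obs, W0_G)
            biases.append(abs(fit.estimates["w_f_max"] - 142.667) / 142.667)
        assert biases[-1] < biases[0]
        assert biases[-1] < 0.01

    def test_first_order_optimality(self):
        design = default_trial_design(seed=3, heterogeneous_sites=False)
        obs, _ = generate_trial(design)
        fit = fit_logistic(obs, W0_G)
        # residuals at the optimum are orthogonal to the Jacobian columns
        rgr, wmax = fit.estimates["rgr_max"], fit.estimates["w_f_max"]
        m = (obs["dap"] >= 7) & (obs["dap"] <= 63)
        dap = obs.loc[m, "dap"].to_numpy(float)
        w = obs.loc[m, "fresh_weight_g"].to_numpy(float)
        resid = biomass_at(dap, W0_G, GrowthParams(rgr, wmax)) - w
        # analytic Jacobian of w(t) = K / (1 + A e^{-rt}), A = (K - w0)/w0
        a = (wmax - W0_G) / W0_G
        e = np.exp(-rgr * dap)
        denom = (1.0 + a * e) ** 2
        d_rgr = wmax * a * dap * e / denom
        d_wmax = 1.0 / (1.0 + a * e) - wmax * e / (W0_G * denom)
        jac = np.column_stack([d_rgr, d_wmax * wmax])  # scale-free columns
        grad = jac.T @ resid
        norm = np.linalg.norm(grad) / (np.linalg.norm(resid) * np.linalg.norm(jac))
        assert norm < 1e-6

    def test_too_few_dates_flagged_not_raised(self):
        obs = noiseless_biomass(schedule=(7, 14))
        fit = fit_logistic(obs, W0_G)
        assert not fit.converged
        assert "distinct dap" in fit.message

    def test_date_means_mode(self):
        obs = noiseless_biomass()
        a = fit_logistic(obs, W0_G, use_date_means=False)
        b = fit_logistic(obs, W0_G, use_date_means=True)
        # identical replicates -> identical estimates either way
        assert a.estimates["rgr_max"] == pytest.approx(
            b.estimates["rgr_max"], rel=1e-9
        )


class TestFitChemical:
    TRUE_C = ChemicalParams(cf_min=0.0831, cf_max=0.202, cfk=0.180, cft50=29.5)

    def test_zero_noise_exact_recovery(self):
        obs = noiseless_chem(self.TRUE_C, schedule=tuple(range(21, 50, 4)))
        fit = fit_chemical(obs)
        assert fit.converged
        for name, truth in [
            ("cf_min", 0.0831), ("cf_max", 0.202), ("cfk", 0.180), ("cft50", 29.5)
        ]:
            assert fit.estimates[name] == pytest.approx(truth, rel=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_fitted_curve_content_at_45(self):
        obs = noiseless_chem(self.TRUE_C, schedule=tuple(range(21, 50, 4)))
        fit = fit_chemical(obs)
        est = ChemicalParams(**{k: fit.estimates[k]
                                for k in ("cf_min", "cf_max", "cfk", "cft50")})
        assert round(float(chemical_fraction(45, est)), 3) == 0.195

    def test_window_excludes_later_dates(self):
        obs = noiseless_chem(self.TRUE_C, schedule=(21, 28, 35, 42, 49, 63, 77))
        corrupted = obs.copy()
        corrupted.loc[corrupted["dap"] > 49, "fraction"] = 0.01
        a = fit_chemical(obs, window=(0, 49))
        b = fit_chemical(corrupted, window=(0, 49))
        assert a.estimates == b.estimates


class TestFitExponential:
    def test_pure_exponential_exact_recovery(self):
        dap = np.array([7, 14, 21, 28, 35], float)
        w = 10.0 * np.exp(0.06 * dap)
        obs = pd.DataFrame(
            {"site": "A", "dap": dap, "replicate": 1, "fresh_weight_g": w,
             "dry_weight_g": np.nan}
        )
        fit = fit_exponential(obs, window=(0, 40))
        assert fit.estimates["rgr"] == pytest.approx(0.06, rel=1e-6)
        assert fit.estimates["w_f0_hat"] == pytest.approx(10.0, rel=1e-6)

    def test_logistic_data_dominates_exponential_on_long_window(self):
        obs = noiseless_biomass()
        exp_fit = fit_exponential(obs, window=(7, 63))
        log_fit = fit_logistic(obs, W0_G, window=(7, 63))
        assert exp_fit.rss > log_fit.rss

    def test_early_window_rate_approaches_rgr_max(self):
        # with a start weight deep in the exponential phase (<1% of the
        # carrying capacity), the early-window exponential rate is close
        # to the logistic rgr_max; at the trial's heavier planting weight
        # the curve has already bent and the rate falls short
        tiny = noiseless_biomass(schedule=(7, 14, 21), w0=1.0)
        fit_tiny = fit_exponential(tiny, window=(0, 21))
        assert fit_tiny.estimates["rgr"] == pytest.approx(0.0778, rel=0.10)
        trial = noiseless_biomass(schedule=(7, 14, 21), w0=W0_G)
        fit_trial = fit_exponential(trial, window=(0, 21))
        assert fit_trial.estimates["rgr"] < fit_tiny.estimates["rgr"]


class TestEstimateMoisture:
    def test_worked_example(self):
        assert estimate_moisture([20.0], [2.0]) == pytest.approx(0.9)

    def test_fully_dry_sample(self):
        assert estimate_moisture([5.0], [5.0]) == 0.0

    def test_recovers_generator_truth(self):
        design = default_trial_design(seed=11, heterogeneous_sites=False)
        obs, _ = generate_trial(design)
        m_f = estimate_moisture(obs["fresh_weight_g"], obs["dry_weight_g"])
        assert m_f == pytest.approx(0.872, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            estimate_moisture([0.0], [0.0])
        with pytest.raises(ValueError):
            estimate_moisture([1.0], [2.0])


class TestPerSiteFit:
    def test_single_site_pooled_equals_site(self):
        obs = noiseless_biomass()
        fits = per_site_fit(obs, W0_G)
        assert set(fits) == {"A", "pooled"}
        assert fits["A"].estimates == fits["pooled"].estimates

    def test_site_ordering_recovered(self):
        """Per-site growth-rate estimates preserve the true ranking of a
        heterogeneous six-site trial (river-mouth gradient)."""
        from scipy.stats import spearmanr

        rhos = []
        for seed in range(20):
            design = default_trial_design(seed=seed)
            obs, _ = generate_trial(design)
            fits = per_site_fit(obs, W0_G)
            truth = [p.rgr_max for p in design.true_params_per_site]
            est = [fits[s].estimates["rgr_max"] for s in design.site_labels]
            rhos.append(spearmanr(truth, est).statistic)
        assert np.mean(rhos) >= 0.8

    def test_pooled_rate_within_site_range(self):
        design = default_trial_design(seed=5)
        obs, _ = generate_trial(design)
        fits = per_site_fit(obs, W0_G)
        rates = [fits[s].estimates["rgr_max"] for s in design.site_labels]
        pooled = fits["pooled"].estimates["rgr_max"]
        assert min(rates) <= pooled <= max(rates)


class TestRgrVsCovariate:
    def test_descriptive_slope_sign(self):
        design = default_trial_design(seed=2)  # rgr decreases with distance
        obs, _ = generate_trial(design)
        fits = per_site_fit(obs, W0_G)
        reg = fit_rgr_vs_covariate(fits, design.site_covariate)
        assert reg["slope"] < 0
        assert reg["n_sites"] == 6
        assert reg["slope_se"] > 0

    def test_needs_three_sites(self):
        obs = noiseless_biomass()
        fits = per_site_fit(obs, W0_G)
        with pytest.raises(ValueError):
            fit_rgr_vs_covariate(fits, {"A": 0.0})
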