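# Methods

## Model structure and assumptions

The simulator chains four deterministic layers:

1. **Growth.** Gross fresh biomass per m² of sea area follows the
   logistic equation with two parameters: the maximum relative growth
   rate `rgr_max` (day⁻¹, the per-unit-biomass rate at low density) and
   the carrying capacity `w_f_max` (kg FW m⁻²). The closed-form sigmoid
   is used throughout; the rate ODE exists only as an independent
   cross-check in the tests (closed form vs `solve_ivp` agrees to
   ≤1e-6 relative over a 120-day cycle). Growth is environment-free:
   temperature, irradiance and nutrients act only through the fitted
   parameter values, and the post-peak biomass decline seen in some
   field sites after ~day 63 is deliberately outside the model.
2. **Scheduling.** A farming year is fixed at 360 days. A cycle of
   `hcl` days includes the harvest day, on which the crop is out of the
   water for sorting and replanting, so each cycle grows for
   `lgp = hcl − 1` days; `hcl = 1` is rejected as pathological (zero
   growing days). Cycle count `360/hcl` is kept real-valued so the
   annual aggregate is a continuous function of `hcl`; days-after-
   planting within the year is the mathematical modulo
   `mod(doy − doy0, hcl)`, non-negative for any inputs.
3. **Post-harvest.** Drying is an instantaneous mass balance (no
   drying kinetics or weather): semi-dry = fresh ×
   `(1 − m_f)/(1 − m_sd)`, which conserves dry matter exactly. Chemical
   content per kg semi-dry follows a four-parameter logistic in crop
   age. `cfk` carries units day⁻¹ (any other unit is dimensionally
   inconsistent in the exponent). The annual chemical harvest evaluates
   the content at `t = hcl`, one day older than the growing period the
   biomass accrues over; this asymmetry is kept as the model's
   convention and `annual_chemical` exposes `cf_eval_day` to override
   it.
4. **Economics.** The farmgate price per kg semi-dry is proportional
   to content, so income can be computed equivalently through semi-dry
   mass × semi-dry price or chemical mass × chemical price; the test
   suite asserts both routes agree to 1e-12. Costs split into a
   continuous maintenance rate `pc_m` (IDR m⁻² day⁻¹) and an
   event-based harvest cost `pc_h` (IDR m⁻² cycle⁻¹), annualised as
   `360·pc_m + (360/hcl)·pc_h`. One deliberate bookkeeping wrinkle:
   when *deriving* `pc_m` from annual farm-level cost totals the
   divisor is the 365-day calendar year (matching how such cost studies
   report), while the simulation annualises over the 360-day farming
   year. Both conventions are kept as-is; re-annualising derived rates
   therefore reconstructs the source totals only to within 1.4%, and a
   test asserts that discrepancy rather than hiding it.

Currency is an opaque label (IDR by default); there is no NPV,
depreciation scheduling or labour/capital split — costs enter only
through the two aggregate rates.

## Reference parameter set

The shipped configuration (`besem/data/gracilaria_takalar.json`) holds
estimates for *Gracilaria* farmed near Takalar, SW Sulawesi:
`rgr_max = 0.0778 day⁻¹`, `w_f_max = 0.951113 kg FW m⁻²` (142.667 g
per plant at 6.67 plants m⁻²), content sigmoid
`cf_min = 0.0831, cf_max = 0.202, cfk = 0.180 day⁻¹, cft50 = 29.5 d`,
moistures `m_f = 0.872217, m_sd = 0.293`, price
`fgp_c = 30,769 IDR kg⁻¹` agar (back-computed from 6,000 IDR kg⁻¹
semi-dry at a 45-day harvest via the rounded content 0.195), costs
`pc_m = 0.658, pc_h = 386.7`, and a 600-line × 25 m × 0.75 m farm
(11,250 m²) at 5 plants per meter of line.

## Unit conventions

kg FW m⁻² and days are canonical internally; gram-per-plant quantities
convert at the interface through the plant density `l_pd / l_w`
(plants m⁻²), e.g. 30 g plant⁻¹ ↔ 0.2 kg m⁻² at 5 plants m⁻¹ on
0.75 m spacing. Scenario grids take replanting weights in kg m⁻² and
report the g-per-plant alias from the same conversion.

## Calibration

Growth fits estimate `(rgr_max, w_f_max)` by nonlinear least squares on
plant-level fresh weights, with the planting weight fixed at its
measured value (plants are weighed at planting, so it is data, not a
parameter); an option fits per-date means instead. The default growth
window is 7–63 days after planting — the window over which field growth
is sigmoid, excluding the unexplained late decline — and the content
window is 0–49 days; both are overridable, and a test asserts that
observations outside the window cannot affect the estimates. Initial
values: the growth rate from a log-linear regression of the
early-window weights (the curve is exponential at low biomass),
capacity at 1.2× the maximum observed weight, content asymptotes at the
observed min/max, midpoint at the median assay day, steepness 0.1.
Bounds: `rgr_max ∈ (0, 1]`, `w_f_max ∈ (0.5, 10]× max observed`,
`cfk ∈ (0, 2]`; a solution pinned at a bound is flagged as
non-converged. Optimiser tolerances are tightened to 1e-12 so the
first-order optimality condition (residuals orthogonal to the Jacobian
columns) holds to 1e-6 on the normalised gradient. Standard errors come
from the Jacobian at the optimum, `s²(JᵀJ)⁻¹`. Non-convergence returns
a flagged result, never an exception, so per-site tables degrade
gracefully.

The exponential model `w = w0·e^(rgr·t)` is fitted as the classical
baseline: nested within the logistic at early times, it is dominated
(higher RSS) on any window long enough to show curvature. Its rate only
approximates `rgr_max` when the start weight sits deep in the
exponential phase (≲1% of capacity); at the reference trial's planting
weight (7.6% of capacity) the early-window rate already falls ~20%
short, which the tests document.

The growth-rate-vs-site-covariate helper is a plain OLS of per-site
`rgr_max` on one scalar (e.g. distance from a river mouth); it reports
slope ± SE with no significance verdict and is descriptive only.

## Synthetic trials

The generator emulates the reference experiment's *structure*: 6 sites,
planting at 10.86 g plant⁻¹, sampling at days
7, 14, 21, 28, 35, 42, 49, 63, 77, 91, 105, 119 with 5 replicate
plants per site per date, chemical assays per site per date from day
21 (earlier samples are too small for extraction). Noise choices, with
rationale:

* Fresh weights: truth × lognormal with unit mean and CV 0.25 —
  multiplicative because weights are positive and scatter grows with
  plant size; the CV level produces fitted-vs-observed scatter of the
  magnitude seen in field trials of this kind.
* Dry weights: fresh × (1 − m_f) × (1 + Gaussian, CV 0.03), clipped to
  [0, fresh] — a small assay error on top of the moisture balance.
* Content: sigmoid truth + Gaussian(0, 0.032) truncated to [0, 1]. The
  SD is set analytically so that, over the day 21–49 assay schedule,
  signal variance / (signal + noise variance) ≈ 0.58 — the explained
  variance the content fit achieves on the field data the generator
  emulates.
* Optional decline: after an onset day the truth decays exponentially
  from its onset value. This is plumbing to exercise fit-window
  discipline, not a biological claim about the real decline.

Per-site heterogeneity defaults to a growth-rate gradient from 0.10
down to 0.05 day⁻¹ (the river-mouth-to-distant spread seen in the
field) with a common carrying capacity, since between-site capacity
differences were not resolvable in the reference data. A fixed seed
makes output bit-reproducible.

What passing recovery tests do **not** show: the generator has no
transplanting-shock lag, no environmental covariance structure, no
within-date correlation between replicates, and its decline is a
caricature — recovery performance on real trials with those features
will be worse than on these synthetics.

## Scenario grids and optima

Grids evaluate every (hcl, w_f0) cell independently by composing the
layers above; invalid cells (e.g. replanting weight at or above the
carrying capacity) record their error per-cell. Optima are the discrete
argmax over the evaluated grid — no continuous optimisation — with ties
broken toward the smaller cycle length, then the smaller replanting
weight, so results are deterministic. Under the reference parameters
the gross-income argmax sits at (45 d, 0.15 kg m⁻²) and the net-income
argmax at (60 d, 0.10 kg m⁻²): charging for each harvest event pushes
the optimum toward fewer, longer cycles and a lighter replant, and the
tests assert this shift is monotone in `pc_h`.

## Problem sizes in the test suite

The Monte-Carlo recovery study runs 200 replicate six-site trials at
CV 0.25 (growth-rate recovery within ±15% in ≥90% of replicates), the
content-fit band uses 30 replicates, the site-ranking check 20 seeds,
and the ensemble-mean convergence check 10⁴ replicates at three dates —
sizes at which the binomial/mean assertions are stable across seeds
while the whole suite stays fast.

## Known limitations

* The 360-day year and the one lost day per cycle are conventions, not
  observations; the lost day is modelled only through `lgp = hcl − 1`
  (no separate out-of-water state).
* Content at harvest is evaluated at `hcl`, not `hcl − 1` (see above).
* No plotting beyond CSV export; figures are presentation, not model.
* Prices and costs are constants; no seasonality, market response or
  discounting.
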