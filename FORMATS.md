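# File formats

All CSV files use `,` as field separator and `.` as decimal separator,
no thousands separators, regardless of locale. All JSON is flat
snake_case.

## Parameter set (JSON)

One flat object; all keys required except `doy0` (default 1). Unknown
keys are rejected on load.

| key | unit | meaning |
|---|---|---|
| `rgr_max` | day⁻¹ | maximum relative growth rate |
| `w_f_max` | kg FW m⁻² | maximum attainable fresh biomass |
| `cf_min`, `cf_max` | kg chem kg⁻¹ SDW | content-sigmoid asymptotes |
| `cfk` | day⁻¹ | content-sigmoid steepness |
| `cft50` | day | content-sigmoid midpoint (days after planting) |
| `m_f`, `m_sd` | kg water kg⁻¹ | moisture, fresh / semi-dry |
| `w_f0` | kg FW m⁻² | default replanting weight |
| `hcl` | day | default harvest cycle length |
| `doy0` | day | default planting day of year |
| `fgp_c` | IDR kg⁻¹ chem | farmgate price of the chemical |
| `pc_m` | IDR m⁻² day⁻¹ | maintenance cost rate |
| `pc_h` | IDR m⁻² cycle⁻¹ | harvest-event cost |
| `l_n`, `l_l`, `l_w`, `l_pd` | –, m, m, m⁻¹ | lines, line length, spacing, plants per m |

The shipped default (`besem/data/gracilaria_takalar.json`) holds the
*Gracilaria* estimates for the Takalar site.

## Biomass observations (CSV)

Columns: `site` (label), `dap` (days after planting, int),
`replicate` (int), `fresh_weight_g` (g plant⁻¹),
`dry_weight_g` (g plant⁻¹, may be empty).

## Chemistry observations (CSV)

Columns: `site`, `dap`, `fraction` (kg chemical kg⁻¹ SDW, in [0, 1]).

## Itemised farm costs (CSV / records)

Columns: `item` (free text), `idr_per_farm_per_year` (number),
`category` (`maintenance` or `harvest`).

## Sawtooth series (CSV, `besem simulate`)

Columns: `doy`, `dap`, `biomass_kg_fw_m2`.

## Scenario grid (CSV, `besem grid`)

One row per (hcl, w_f0) cell. Columns: `hcl`, `w_f0`, `w_f0_g_plant`,
`n_h`, `gross_per_cycle`, `net_per_cycle`, `fraction_sold`,
`annual_net_fresh`, `annual_net_sd`, `annual_chem`, `gross_income`,
`net_income`, `error` (empty for valid cells; invalid cells carry the
message here and NaN metrics).

## Fit results (JSON, `besem fit`)

Object with `estimates`, `standard_errors` (parameter name → value),
`n_obs`, `fit_window` `[lo, hi]`, `converged`, `rss`, `r_squared`
(chemistry fits), `message`. Biomass fits with dry weights present are
wrapped as `{"fit": ..., "m_f": ...}`.
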