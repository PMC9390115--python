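"""Management-scenario grids and optimum finding.

Runs the full bio-economic chain over a grid of farmer decisions —
harvest cycle length × replanting weight — and reports per-cycle and
annual yields (fresh, semi-dry, chemical) and gross/net income for each
cell, plus the argmax cell for any metric.  Replanting weights are
specified in kg FW m⁻² (authoritative) with g plant⁻¹ aliases derived
from the farm geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import GrowthParams, ManagementPlan, annual_net_fresh
from .postharvest import (
    ChemicalParams,
    MoistureParams,
    chemical_fraction,
    fresh_to_semidry,
)
from .economics import (
    EconomicParams,
    FarmGeometry,
    farmgate_price,
    per_area_to_per_plant,
    production_cost,
)

__all__ = ["ScenarioGrid", "run_grid", "find_optimum", "table6_report", "METRICS"]

METRICS = (
    "annual_net_fresh",
    "annual_net_sd",
    "annual_chem",
    "gross_income",
    "net_income",
)

_CELL_COLUMNS = [
    "hcl",
    "w_f0",
    "w_f0_g_plant",
    "n_h",
    "gross_per_cycle",
    "net_per_cycle",
    "fraction_sold",
    "annual_net_fresh",
    "annual_net_sd",
    "annual_chem",
    "gross_income",
    "net_income",
    "error",
]


@dataclass
class ScenarioGrid:
    """Results of a (hcl × w_f0) management grid.

    ``cells`` holds one row per grid cell with all yield and income
    metrics; cells whose parameters violate model invariants carry the
    error message in the ``error`` column and NaN metrics instead of
    failing the whole grid.
    """

    hcl_values: list[int]
    w_f0_values: list[float]
    cells: pd.DataFrame = field(repr=False)

    def cell(self, hcl: int, w_f0: float) -> pd.Series:
        """Return the record for one (hcl, w_f0) combination."""
        m = (self.cells["hcl"] == hcl) & np.isclose(self.cells["w_f0"], w_f0)
        if not m.any():
            raise KeyError(f"no cell ({hcl}, {w_f0}) in grid")
        return self.cells[m].iloc[0]


def _evaluate_cell(
    hcl: int,
    w_f0: float,
    growth: GrowthParams,
    moisture: MoistureParams,
    chem: ChemicalParams,
    econ: EconomicParams,
    geom: FarmGeometry | None,
) -> dict:
    plan = ManagementPlan(hcl=hcl, w_f0=w_f0)
    y = annual_net_fresh(plan, growth)
    annual_sd = fresh_to_semidry(y.annual_net_fresh, moisture)
    fgp_sd = farmgate_price(hcl, chem, econ)
    gross = annual_sd * fgp_sd
    cost = production_cost(hcl, econ)
    return {
        "hcl": hcl,
        "w_f0": w_f0,
        "w_f0_g_plant": per_area_to_per_plant(w_f0, geom) if geom else np.nan,
        "n_h": y.n_h,
        "gross_per_cycle": y.gross_per_cycle,
        "net_per_cycle": y.net_per_cycle,
        "fraction_sold": y.fraction_sold,
        "annual_net_fresh": y.annual_net_fresh,
        "annual_net_sd": annual_sd,
        "annual_chem": float(chemical_fraction(hcl, chem)) * annual_sd,
        "gross_income": gross,
        "net_income": gross - cost,
        "error": "",
    }


def run_grid(
    hcl_values: Sequence[int],
    w_f0_values: Sequence[float],
    growth: GrowthParams,
    moisture: MoistureParams,
    chem: ChemicalParams,
    econ: EconomicParams,
    geom: FarmGeometry | None = None,
) -> ScenarioGrid:
    """Evaluate the bio-economic model on every (hcl, w_f0) combination.

    Deterministic; cells are independent, so evaluation order does not
    affect results.  A cell with invalid parameters (e.g. a replanting
    weight at or above the carrying capacity) is recorded with its error
    message rather than aborting the grid.
    """
    rows = []
    for hcl in hcl_values:
        for w_f0 in w_f0_values:
            try:
                rows.append(
                    _evaluate_cell(hcl, w_f0, growth, moisture, chem, econ, geom)
                )
            except ValueError as exc:
                row = {c: np.nan for c in _CELL_COLUMNS}
                row.update({"hcl": hcl, "w_f0": w_f0, "error": str(exc)})
                rows.append(row)
    cells = pd.DataFrame(rows, columns=_CELL_COLUMNS)
    return ScenarioGrid(
        hcl_values=list(hcl_values), w_f0_values=list(w_f0_values), cells=cells
    )


def find_optimum(grid: ScenarioGrid, metric: str) -> tuple[int, float, float]:
    """Argmax cell of a metric over the grid: (hcl, w_f0, value).

    Ties are broken deterministically toward the smaller ``hcl``, then
    the smaller ``w_f0``.  Error cells are ignored.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    ok = grid.cells[grid.cells["error"] == ""]
    if ok.empty:
        raise ValueError("grid has no valid cells")
    # tie-break order is (hcl, w_f0) ascending regardless of how the
    # grid was constructed
    ordered = ok.sort_values(["hcl", "w_f0"], kind="stable")
    best = ordered[ordered[metric] == ordered[metric].max()].iloc[0]
    return int(best["hcl"]), float(best["w_f0"]), float(best[metric])


def table6_report(
    w_f0: float,
    hcl_values: Sequence[int],
    growth: GrowthParams,
) -> pd.DataFrame:
    """Annual yield accounting table for one replanting weight.

    One row per cycle length with harvests/year, gross and net yield per
    cycle and per year (2 dp) and the fraction of the harvest sold
    (percent, 0 dp) — the format in which such aggregates are usually
    tabulated.
    """
    rows = []
    for hcl in hcl_values:
        y = annual_net_fresh(ManagementPlan(hcl=hcl, w_f0=w_f0), growth)
        rows.append(
            {
                "cycle_days": hcl,
                "harvests_per_year": round(y.n_h, 2),
                "gross_per_cycle": round(y.gross_per_cycle, 2),
                "net_per_cycle": round(y.net_per_cycle, 2),
                "gross_annual": round(y.n_h * y.gross_per_cycle, 2),
                "net_annual": round(y.annual_net_fresh, 2),
                "fraction_sold_pct": int(round(y.fraction_sold * 100)),
            }
        )
    return pd.DataFrame(rows)
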