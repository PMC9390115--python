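"""Farm economics: prices, costs, income and geometry conversions.

All quantities are carried per square meter of sea area so that
cultivation systems with different line spacings (or no lines at all)
are directly comparable.  The farmgate price per kg semi-dry seaweed is
proportional to its chemical content, so early harvests fetch a lower
price.  Production costs split into continuous "maintenance" costs
(IDR m⁻² day⁻¹: depreciation plus daily line care) and event-based
"harvest" costs (IDR m⁻² cycle⁻¹: harvesting, drying, re-tying and
replanting labour), annualised over a 360-day year:

    PC(hcl) = 360·PC_m + (360/hcl)·PC_h
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .growth import YEAR_DAYS, GrowthParams, ManagementPlan, annual_net_fresh
from .postharvest import (
    ChemicalParams,
    MoistureParams,
    chemical_fraction,
    fresh_to_semidry,
)

__all__ = [
    "EconomicParams",
    "FarmGeometry",
    "farmgate_price",
    "gross_income",
    "production_cost",
    "net_income",
    "farm_area",
    "per_plant_to_per_area",
    "per_area_to_per_plant",
    "derive_economic_params",
]

#: Calendar year length used when deriving daily cost rates from annual
#: farm-level cost totals.  The simulation itself annualises over the
#: 360-day farming year; keeping both conventions reproduces the source
#: bookkeeping exactly, at the price of a documented <=1.4% mismatch
#: when round-tripping cost totals.
CALENDAR_DAYS = 365


@dataclass(frozen=True)
class EconomicParams:
    """Price and cost rates (currency is an opaque label, default IDR).

    fgp_c : farmgate price of the pure chemical, IDR kg⁻¹ chemical.
    pc_m : maintenance cost, IDR m⁻² day⁻¹.
    pc_h : harvest-event cost, IDR m⁻² cycle⁻¹.
    """

    fgp_c: float
    pc_m: float
    pc_h: float
    currency: str = "IDR"

    def __post_init__(self) -> None:
        for name in ("fgp_c", "pc_m", "pc_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class FarmGeometry:
    """Line layout of the farm.

    l_n : number of lines; l_l : line length (m); l_w : spacing between
    lines (m); l_pd : plants per meter of line.
    """

    l_n: float
    l_l: float
    l_w: float
    l_pd: float

    def __post_init__(self) -> None:
        for name in ("l_n", "l_l", "l_w", "l_pd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def plant_density(self) -> float:
        """Plants per m² of sea area, l_pd / l_w."""
        return self.l_pd / self.l_w


def farmgate_price(t: float, chem: ChemicalParams, econ: EconomicParams) -> float:
    """Price per kg semi-dry seaweed harvested at ``t`` days after planting.

    Proportional to chemical content: ``FGP_sd(t) = FGP_c · cf(t)``.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return econ.fgp_c * float(chemical_fraction(t, chem))


def gross_income(
    plan: ManagementPlan,
    growth: GrowthParams,
    moisture: MoistureParams,
    chem: ChemicalParams,
    econ: EconomicParams,
) -> float:
    """Gross annual income (IDR m⁻² year⁻¹).

    Annual net semi-dry yield times the content-dependent farmgate price
    at harvest age ``hcl``; algebraically identical to annual chemical
    production times the chemical price.
    """
    w_fn = annual_net_fresh(plan, growth).annual_net_fresh
    w_sdn = fresh_to_semidry(w_fn, moisture)
    return w_sdn * farmgate_price(plan.hcl, chem, econ)


def production_cost(hcl: int, econ: EconomicParams) -> float:
    """Annual production cost (IDR m⁻² year⁻¹): 360·pc_m + (360/hcl)·pc_h.

    Strictly decreasing in ``hcl`` when harvest costs are positive —
    fewer cycles mean fewer harvest events.
    """
    if hcl < 2:
        raise ValueError(f"hcl must be >= 2, got {hcl}")
    return YEAR_DAYS * econ.pc_m + (YEAR_DAYS / hcl) * econ.pc_h


def net_income(
    plan: ManagementPlan,
    growth: GrowthParams,
    moisture: MoistureParams,
    chem: ChemicalParams,
    econ: EconomicParams,
) -> float:
    """Net annual income (IDR m⁻² year⁻¹); may be negative."""
    return gross_income(plan, growth, moisture, chem, econ) - production_cost(
        plan.hcl, econ
    )


def farm_area(geom: FarmGeometry) -> float:
    """Sea area occupied by the farm (m²): lines × length × spacing."""
    return geom.l_n * geom.l_l * geom.l_w


def per_plant_to_per_area(w_plant_g: float, geom: FarmGeometry) -> float:
    """Convert g plant⁻¹ to kg m⁻² using the plant density l_pd/l_w."""
    if w_plant_g < 0:
        raise ValueError("weight must be >= 0")
    return 0.001 * w_plant_g * geom.plant_density


def per_area_to_per_plant(w_area_kg: float, geom: FarmGeometry) -> float:
    """Convert kg m⁻² to g plant⁻¹ (inverse of :func:`per_plant_to_per_area`)."""
    if w_area_kg < 0:
        raise ValueError("weight must be >= 0")
    return 1000.0 * w_area_kg / geom.plant_density


def derive_economic_params(
    farm_level_costs: Iterable[Mapping],
    n_harvests_per_year: float,
    geom: FarmGeometry,
    fgp_sd_at_t: float,
    t_ref: float,
    chem: ChemicalParams,
) -> EconomicParams:
    """Aggregate itemised annual farm costs into per-m² rate parameters.

    Parameters
    ----------
    farm_level_costs
        Records with keys ``item``, ``idr_per_farm_per_year`` and
        ``category`` in {"maintenance", "harvest"} — e.g. rows of a
        detailed farm-level economic study.
    n_harvests_per_year
        Harvest count of the source system the cost totals refer to.
    fgp_sd_at_t, t_ref
        Observed farmgate price per kg semi-dry at a reference harvest
        age ``t_ref`` (days); the chemical price is recovered as
        ``fgp_sd / cf(t_ref)``.

    Maintenance totals are spread over a 365-day calendar year to give a
    daily rate; harvest totals are divided by the harvest count.
    """
    area = farm_area(geom)
    if area <= 0:
        raise ValueError("farm area must be positive")
    if n_harvests_per_year < 1:
        raise ValueError("n_harvests_per_year must be >= 1")
    totals = {"maintenance": 0.0, "harvest": 0.0}
    for row in farm_level_costs:
        cat = row["category"]
        if cat not in totals:
            raise ValueError(
                f"unknown cost category {cat!r} for item {row.get('item')!r}"
            )
        totals[cat] += float(row["idr_per_farm_per_year"])
    pc_m = totals["maintenance"] / area / CALENDAR_DAYS
    pc_h = totals["harvest"] / area / n_harvests_per_year
    fgp_c = fgp_sd_at_t / float(chemical_fraction(t_ref, chem))
    return EconomicParams(fgp_c=fgp_c, pc_m=pc_m, pc_h=pc_h)
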