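"""Drying mass balance and chemical-content model.

Harvested seaweed is sun-dried on beach platforms before sale.  Drying
is modelled as an instantaneous mass balance: dry matter is conserved,
only water is removed, so the fresh→semi-dry conversion factor is
``(1 − m_f)/(1 − m_sd)`` with ``m_f`` the moisture fraction fresh from
sea and ``m_sd`` the moisture fraction of the semi-dry product.

The content of the extractable chemical (agar in *Gracilaria*,
carrageenan in *Kappaphycus*) per kg semi-dry weight rises with crop age
along a four-parameter sigmoid from ``cf_min`` toward ``cf_max``, with
midpoint at ``cft50`` days after planting and steepness ``cfk`` (day⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth import GrowthParams, ManagementPlan, annual_net_fresh

__all__ = [
    "MoistureParams",
    "ChemicalParams",
    "fresh_to_semidry",
    "chemical_fraction",
    "annual_chemical",
]


@dataclass(frozen=True)
class MoistureParams:
    """Moisture fractions (kg water per kg of product).

    ``m_f``: fresh from sea; ``m_sd``: after beach drying.
    Must satisfy 0 ≤ m_sd < 1 and m_sd ≤ m_f < 1 (drying removes water).
    """

    m_f: float
    m_sd: float

    def __post_init__(self) -> None:
        if not 0 <= self.m_f < 1:
            raise ValueError(f"m_f must be in [0, 1), got {self.m_f}")
        if not 0 <= self.m_sd < 1:
            raise ValueError(f"m_sd must be in [0, 1), got {self.m_sd}")
        if self.m_sd > self.m_f:
            raise ValueError(
                f"semi-dry moisture m_sd={self.m_sd} cannot exceed fresh "
                f"moisture m_f={self.m_f}"
            )

    @property
    def conversion(self) -> float:
        """Fresh→semi-dry mass conversion factor (1 − m_f)/(1 − m_sd)."""
        return (1.0 - self.m_f) / (1.0 - self.m_sd)


@dataclass(frozen=True)
class ChemicalParams:
    """Sigmoid model of chemical content vs days after planting.

    ``cf(t) = cf_min + (cf_max − cf_min) / (1 + e^(−cfk·(t − cft50)))``

    Attributes
    ----------
    cf_min, cf_max : float
        Asymptotic content fractions (kg chemical per kg SDW) at
        t → −∞ and t → +∞ respectively.
    cfk : float
        Slope steepness (day⁻¹).
    cft50 : float
        Days after planting at which content is halfway between
        ``cf_min`` and ``cf_max``.
    label : str
        Free-text identity of the chemical (e.g. "agar"); carries no
        behaviour.
    """

    cf_min: float
    cf_max: float
    cfk: float
    cft50: float
    label: str = "agar"

    def __post_init__(self) -> None:
        if not 0 <= self.cf_min < self.cf_max <= 1:
            raise ValueError(
                f"need 0 <= cf_min < cf_max <= 1, got "
                f"cf_min={self.cf_min}, cf_max={self.cf_max}"
            )
        if not self.cfk > 0:
            raise ValueError(f"cfk must be > 0, got {self.cfk}")
        if not self.cft50 > 0:
            raise ValueError(f"cft50 must be > 0, got {self.cft50}")


def fresh_to_semidry(w_fresh, moisture: MoistureParams):
    """Convert a fresh weight to semi-dry weight, conserving dry matter.

    ``(1 − m_f)·w_fresh`` kg of dry matter ends up in ``result`` kg of
    semi-dry product at moisture ``m_sd``.
    """
    w_fresh = np.asarray(w_fresh, dtype=float)
    if np.any(w_fresh < 0):
        raise ValueError("fresh weight must be >= 0")
    out = w_fresh * moisture.conversion
    return out if out.ndim else float(out)


def chemical_fraction(t, chem: ChemicalParams):
    """Chemical content (kg chemical kg⁻¹ SDW) at ``t`` days after planting.

    Strictly increasing in ``t``; equals ``(cf_min + cf_max)/2`` exactly
    at ``t = cft50``.  Negative ``t`` is allowed for diagnostics.
    """
    t = np.asarray(t, dtype=float)
    out = chem.cf_min + (chem.cf_max - chem.cf_min) / (
        1.0 + np.exp(-chem.cfk * (t - chem.cft50))
    )
    return out if out.ndim else float(out)


def annual_chemical(
    plan: ManagementPlan,
    growth: GrowthParams,
    moisture: MoistureParams,
    chem: ChemicalParams,
    cf_eval_day: float | None = None,
) -> float:
    """Annual harvested chemical (kg m⁻² year⁻¹).

    The annual net semi-dry yield is multiplied by the chemical content
    at harvest.  Content is evaluated at ``t = hcl`` by convention
    (the yield itself accrues over ``hcl − 1`` growing days); pass
    ``cf_eval_day`` to evaluate the sigmoid at a different crop age.
    """
    if cf_eval_day is None:
        cf_eval_day = plan.hcl
    w_fn = annual_net_fresh(plan, growth).annual_net_fresh
    w_sdn = fresh_to_semidry(w_fn, moisture)
    return float(chemical_fraction(cf_eval_day, chem)) * w_sdn
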