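"""Parameter-set serialisation.

A full model configuration is a flat JSON object with snake_case keys
(``rgr_max``, ``w_f_max``, ``cf_min`` … ``l_pd``) mapping one-to-one to
the model parameters; see FORMATS.md for the schema.  A default set
calibrated for *Gracilaria* in the Takalar region ships with the
package.  Cross-parameter invariants (e.g. the replanting weight lying
below the carrying capacity) are enforced on load, and unknown keys are
rejected by name.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

from .growth import GrowthParams, ManagementPlan
from .postharvest import ChemicalParams, MoistureParams
from .economics import EconomicParams, FarmGeometry

__all__ = ["ParameterSet", "load_parameters", "save_parameters", "default_parameters"]

_KEYS = {
    "rgr_max", "w_f_max",
    "cf_min", "cf_max", "cfk", "cft50",
    "m_f", "m_sd",
    "w_f0", "hcl", "doy0",
    "fgp_c", "pc_m", "pc_h",
    "l_n", "l_l", "l_w", "l_pd",
}
_OPTIONAL = {"doy0"}


@dataclass(frozen=True)
class ParameterSet:
    """One complete model configuration."""

    growth: GrowthParams
    moisture: MoistureParams
    chem: ChemicalParams
    econ: EconomicParams
    geom: FarmGeometry
    plan_defaults: ManagementPlan

    def to_flat_dict(self) -> dict:
        d = {}
        d.update(asdict(self.growth))
        m = asdict(self.moisture)
        d.update({"m_f": m["m_f"], "m_sd": m["m_sd"]})
        c = asdict(self.chem)
        d.update({k: c[k] for k in ("cf_min", "cf_max", "cfk", "cft50")})
        e = asdict(self.econ)
        d.update({k: e[k] for k in ("fgp_c", "pc_m", "pc_h")})
        d.update(asdict(self.geom))
        p = asdict(self.plan_defaults)
        d.update({"w_f0": p["w_f0"], "hcl": p["hcl"], "doy0": p["doy0"]})
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "ParameterSet":
        unknown = set(d) - _KEYS
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = _KEYS - _OPTIONAL - set(d)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        try:
            growth = GrowthParams(rgr_max=d["rgr_max"], w_f_max=d["w_f_max"])
            moisture = MoistureParams(m_f=d["m_f"], m_sd=d["m_sd"])
            chem = ChemicalParams(
                cf_min=d["cf_min"], cf_max=d["cf_max"],
                cfk=d["cfk"], cft50=d["cft50"],
            )
            econ = EconomicParams(fgp_c=d["fgp_c"], pc_m=d["pc_m"], pc_h=d["pc_h"])
            geom = FarmGeometry(
                l_n=d["l_n"], l_l=d["l_l"], l_w=d["l_w"], l_pd=d["l_pd"]
            )
            plan = ManagementPlan(
                hcl=d["hcl"], w_f0=d["w_f0"], doy0=d.get("doy0", 1)
            )
            plan.validate_against(growth)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid parameter set: {exc}") from exc
        return cls(
            growth=growth, moisture=moisture, chem=chem,
            econ=econ, geom=geom, plan_defaults=plan,
        )


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a parameter set from a flat JSON file, enforcing invariants."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed parameter file {path}: {exc}") from exc
    return ParameterSet.from_flat_dict(d)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as flat JSON; save→load round-trips exactly."""
    with open(path, "w") as fh:
        json.dump(params.to_flat_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def default_parameters() -> ParameterSet:
    """The shipped *Gracilaria* (Takalar) parameter set."""
    ref = resources.files("besem.data") / "gracilaria_takalar.json"
    return ParameterSet.from_flat_dict(json.loads(ref.read_text()))
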