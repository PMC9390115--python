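import pytest

from besem import (
    ChemicalParams,
    EconomicParams,
    FarmGeometry,
    GrowthParams,
    MoistureParams,
)

GRID_HCL = [5, 15, 30, 45, 60, 90, 120]
GRID_WF0 = [0.005, 0.01, 0.05, 0.10, 0.15, 0.2, 0.5]


@pytest.fixture(scope="session")
def growth():
    """Pooled Gracilaria growth parameters (per-m² scale)."""
    return GrowthParams(rgr_max=0.0778, w_f_max=0.951113)


@pytest.fixture(scope="session")
def growth_per_plant():
    """Same growth parameters on the g-per-plant scale."""
    return GrowthParams(rgr_max=0.0778, w_f_max=142.667)


@pytest.fixture(scope="session")
def moisture():
    return MoistureParams(m_f=0.872217, m_sd=0.293)


@pytest.fixture(scope="session")
def chem():
    return ChemicalParams(cf_min=0.0831, cf_max=0.202, cfk=0.180, cft50=29.5)


@pytest.fixture(scope="session")
def econ():
    return EconomicParams(fgp_c=30769, pc_m=0.658, pc_h=386.7)


@pytest.fixture(scope="session")
def geom():
    return FarmGeometry(l_n=600, l_l=25, l_w=0.75, l_pd=5)
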