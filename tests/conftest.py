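import pytest

from seaweed_cdr.carbonate import SeawaterConditions, solve_carbonate_system
from seaweed_cdr.synth import SynthSpec, synth_biomass_series, synth_gridded_fields

#: the subtropical reference state used throughout (TA/DIC in µmol/kg)
REF_TA = 2350.0
REF_DIC = 2047.5


@pytest.fixture(scope="session")
def ref_conditions():
    return SeawaterConditions(salinity=35.0, temperature=25.0)


@pytest.fixture(scope="session")
def ref_state(ref_conditions):
    """Solved carbonate state at the subtropical reference conditions."""
    return solve_carbonate_system(REF_TA, REF_DIC, ref_conditions)


@pytest.fixture(scope="session")
def bloom_series():
    return synth_biomass_series(SynthSpec(seed=0))


@pytest.fixture(scope="session")
def coarse_fields():
    """Synthetic gridded fields on a coarse (5°) grid to keep tests quick."""
    return synth_gridded_fields(SynthSpec(seed=0, grid_res=5.0))
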