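import numpy as np
import pytest

from morphotx import AtrophySpec, make_atlas, simulate_cohort


@pytest.fixture(scope="session")
def small_atlas():
    """20 cortical + 2 subcortical regions per hemisphere (44 total)."""
    return make_atlas(20, 2, seed=7)


@pytest.fixture(scope="session")
def cortex_only_atlas():
    return make_atlas(30, 0, seed=3)


@pytest.fixture(scope="session")
def planted_cohort(small_atlas):
    """A cohort with strong atrophy planted on 5 left cortical regions."""
    left_cortical = small_atlas.region_ids[
        small_atlas.mask(hemisphere="left", tissue_class="cortical")
    ]
    planted = tuple(int(r) for r in left_cortical[:5])
    spec = AtrophySpec(planted, effect_size=2.0)
    subjects = simulate_cohort(
        small_atlas,
        {"HC": 40, "FBTCS-": 20, "FBTCS+": 30},
        atrophy_specs={"FBTCS-": spec, "FBTCS+": spec},
        seed=11,
    )
    return subjects, planted


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
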