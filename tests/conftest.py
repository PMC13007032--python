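import numpy as np
import pytest

from slabpmf import AnalyticProfileSpec, SlabSystemSpec, kT


@pytest.fixture(scope="session")
def kt300() -> float:
    return kT(300.0)


@pytest.fixture(scope="session")
def flat_profile() -> AnalyticProfileSpec:
    return AnalyticProfileSpec("flat", (-20.0, 20.0))


@pytest.fixture(scope="session")
def double_well(kt300) -> AnalyticProfileSpec:
    """Barrier of 5 k_BT between wells 10 Å apart on a 20 Å domain."""
    return AnalyticProfileSpec(
        "double_well", (-10.0, 10.0),
        {"barrier": 5.0 * kt300, "well_separation": 10.0},
    )


@pytest.fixture(scope="session")
def slab_spec() -> SlabSystemSpec:
    return SlabSystemSpec(seed=11, solute_tilt0=30.0, solute_xi0=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
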