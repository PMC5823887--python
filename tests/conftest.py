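import numpy as np
import pytest

from deltacle import RateConstants, WellMixedState, egfr_parameters


@pytest.fixture(scope="session")
def egfr() -> RateConstants:
    return egfr_parameters()


@pytest.fixture()
def impulse_init() -> WellMixedState:
    """Ligand impulse experiment: resting receptor pool plus 10,000 ligands."""
    return WellMixedState(t=0.0, R=200_000, C=0, L=10_000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1)
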