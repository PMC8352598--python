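import numpy as np
import pytest

from rivalsim import ModelParams


@pytest.fixture(scope="session")
def table_params() -> ModelParams:
    """Fitted parameters of the hierarchical model (package defaults)."""
    return ModelParams()


@pytest.fixture(scope="session")
def decoupled_params() -> ModelParams:
    """All couplings zero: four independent pools at their baseline potentials."""
    return ModelParams(
        w_vis=0.0, w_exc=0.0, w_inh=0.0, w_comp=0.0, w_coop=0.0, w_supp=0.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
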