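import numpy as np
import pytest

from thermotax import ModelParams, TrimerComposition


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def tar_only() -> TrimerComposition:
    return TrimerComposition(n_tar=3, weight=1.0)


@pytest.fixture
def no_ligand() -> dict:
    return {"Tar": 0.0, "Tsr": 0.0}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
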