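import numpy as np
import pytest

from pairsite.model import EmbeddingMatrix, ModelConfig, init_model


@pytest.fixture
def small_config() -> ModelConfig:
    return ModelConfig(embed_dim=8, num_heads=2, mlp_hidden=8, dropout_rate=0.0)


@pytest.fixture
def small_params(small_config):
    return init_model(small_config, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def make_embedding(rng):
    def _make(L: int, d: int, sequence_id: str = "seq") -> EmbeddingMatrix:
        return EmbeddingMatrix(sequence_id=sequence_id, values=rng.standard_normal((L, d)))

    return _make
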