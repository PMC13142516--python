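import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairsite.model import (
    ConfigurationError,
    EmbeddingMatrix,
    ModelConfig,
    backward,
    count_parameters,
    cross_attention,
    forward,
    init_model,
    per_head_norms,
    predict_pair,
)
from pairsite.training import bce_loss

from .reference import loop_forward


class TestConfig:
    def test_head_dim_derived(self):
        assert ModelConfig(embed_dim=1280, num_heads=16).head_dim == 80

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(embed_dim=10, num_heads=3)

    def test_mlp_hidden_defaults_to_embed_dim(self):
        assert ModelConfig(embed_dim=64, num_heads=4).mlp_hidden == 64

    @pytest.mark.parametrize("rate", [-0.1, 1.0])
    def test_dropout_bounds(self, rate):
        with pytest.raises(ConfigurationError):
            ModelConfig(embed_dim=8, num_heads=2, dropout_rate=rate)


class TestInit:
    def test_deterministic_and_shaped(self, small_config):
        a = init_model(small_config, seed=1)
        b = init_model(small_config, seed=1)
        assert a.W_Q.shape == (8, 8)
        for name, arr in a.as_dict().items():
            np.testing.assert_array_equal(arr, b.as_dict()[name])

    def test_output_bias_init_honored(self):
        cfg = ModelConfig(embed_dim=8, num_heads=2, output_bias_init=-3.5)
        assert init_model(cfg, seed=0).mlp_b2[0] == -3.5


class TestParameterAccounting:
    def test_small_config_hand_count(self):
        total, attn, mlp = count_parameters(ModelConfig(embed_dim=8, num_heads=2, mlp_hidden=8))
        assert (total, attn, mlp) == (385, 304, 81)

    def test_full_scale_budget(self):
        total, attn, mlp = count_parameters(ModelConfig())
        assert total == 8_202_241
        assert round(total / 1e6, 2) == 8.20
        assert abs(100.0 * attn / total - 80.0) < 0.5

    @pytest.mark.parametrize("d,heads,hidden", [(8, 2, 8), (16, 4, 32), (12, 3, 5), (64, 16, 64)])
    def test_matches_instantiated_model(self, d, heads, hidden):
        cfg = ModelConfig(embed_dim=d, num_heads=heads, mlp_hidden=hidden)
        total, _, _ = count_parameters(cfg)
        assert total == init_model(cfg, seed=0).n_trainable()


class TestCrossAttention:
    def test_zero_query_key_gives_uniform_rows(self, small_config, small_params, make_embedding):
        p = small_params.copy()
        p.W_Q[...] = 0.0
        p.b_Q[...] = 0.0
        p.W_K[...] = 0.0
        p.b_K[...] = 0.0
        EA, EB = make_embedding(3, 8), make_embedding(5, 8)
        _, attention = cross_attention(EA, EB, p, small_config)
        np.testing.assert_allclose(attention, 1.0 / 5.0, atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        la=st.integers(1, 6), lb=st.integers(1, 6),
        seed=st.integers(0, 2**16), scale_seed=st.floats(0.1, 10.0),
    )
    def test_attention_rows_normalized(self, la, lb, seed, scale_seed):
        cfg = ModelConfig(embed_dim=8, num_heads=2, dropout_rate=0.0)
        params = init_model(cfg, seed=3)
        g = np.random.default_rng(seed)
        EA = EmbeddingMatrix("a", scale_seed * g.standard_normal((la, 8)))
        EB = EmbeddingMatrix("b", scale_seed * g.standard_normal((lb, 8)))
        _, attention = cross_attention(EA, EB, params, cfg)
        assert attention.shape == (2, la, lb)
        np.testing.assert_allclose(attention.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(attention >= 0)

    def test_dimension_mismatch_rejected(self, small_config, small_params, make_embedding):
        with pytest.raises(ValueError):
            cross_attention(
                make_embedding(3, 4), make_embedding(3, 8), small_params, small_config
            )


class TestPredictPair:
    def test_zero_params_give_half(self, small_config, make_embedding):
        p = init_model(small_config, seed=0)
        for name, arr in p.as_dict().items():
            arr[...] = 0.0
        track = predict_pair(make_embedding(4, 8), make_embedding(6, 8), p, small_config)
        np.testing.assert_allclose(track.probabilities, 0.5, atol=1e-12)

    def test_partner_permutation_invariance(self, small_config, small_params, make_embedding, rng):
        EA, EB = make_embedding(5, 8), make_embedding(7, 8)
        base = predict_pair(EA, EB, small_params, small_config).probabilities
        perm = rng.permutation(7)
        shuffled = EmbeddingMatrix("b", EB.values[perm])
        out = predict_pair(EA, shuffled, small_params, small_config).probabilities
        np.testing.assert_allclose(out, base, atol=1e-10)

    def test_query_permutation_equivariance(self, small_config, small_params, make_embedding, rng):
        EA, EB = make_embedding(6, 8), make_embedding(4, 8)
        base = predict_pair(EA, EB, small_params, small_config).probabilities
        perm = rng.permutation(6)
        out = predict_pair(
            EmbeddingMatrix("a", EA.values[perm]), EB, small_params, small_config
        ).probabilities
        np.testing.assert_allclose(out, base[perm], atol=1e-10)


class TestForwardOracle:
    @pytest.mark.parametrize("case", range(8))
    def test_matches_dense_loop_implementation(self, case):
        g = np.random.default_rng(100 + case)
        d = int(g.integers(1, 5)) * 2
        heads = int(g.choice([1, 2]))
        la, lb = int(g.integers(1, 6)), int(g.integers(1, 6))
        cfg = ModelConfig(embed_dim=d, num_heads=heads, mlp_hidden=int(g.integers(1, 9)),
                          dropout_rate=0.0)
        params = init_model(cfg, seed=case)
        for name, arr in params.as_dict().items():
            arr[...] = g.standard_normal(arr.shape)
        EA, EB = g.standard_normal((la, d)), g.standard_normal((lb, d))
        ours, _ = forward(EA, EB, params, cfg)
        theirs = loop_forward(EA, EB, params, cfg)
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestGradients:
    def test_backward_matches_finite_differences(self, small_config):
        g = np.random.default_rng(5)
        params = init_model(small_config, seed=5)
        EA, EB = g.standard_normal((4, 8)), g.standard_normal((3, 8))
        labels = g.integers(0, 2, size=4).astype(float)
        _, cache = forward(EA, EB, params, small_config)
        grads = backward(cache, labels, params, small_config)

        def loss():
            p, _ = forward(EA, EB, params, small_config)
            return bce_loss(p, labels)

        eps = 1e-6
        for name, arr in params.as_dict().items():
            flat = arr.ravel()
            for idx in np.linspace(0, flat.size - 1, num=min(3, flat.size)).astype(int):
                old = flat[idx]
                flat[idx] = old + eps
                up = loss()
                flat[idx] = old - eps
                down = loss()
                flat[idx] = old
                numeric = (up - down) / (2 * eps)
                analytic = grads[name].ravel()[idx]
                assert abs(numeric - analytic) < 1e-6, name


class TestPerHeadNorms:
    def test_zero_params_zero_norms(self, small_config):
        p = init_model(small_config, seed=0)
        for arr in p.as_dict().values():
            arr[...] = 0.0
        table, summary = per_head_norms(p, small_config)
        assert (table.l2_norm == 0).all()
        assert summary["Q"] == (0.0, 0.0)

    def test_identity_single_head(self):
        cfg = ModelConfig(embed_dim=4, num_heads=1)
        p = init_model(cfg, seed=0)
        p.W_Q[...] = np.eye(4)
        table, _ = per_head_norms(p, cfg)
        q = table[(table.projection == "Q")].l2_norm.iloc[0]
        assert q == pytest.approx(2.0)

    def test_matches_elementwise_sum_of_squares(self, small_config, small_params):
        table, _ = per_head_norms(small_params, small_config)
        dh = small_config.head_dim
        mats = {"Q": small_params.W_Q, "K": small_params.W_K, "V": small_params.W_V}
        for _, row in table.iterrows():
            W = mats[row["projection"]]
            h = int(row["head"])
            block = W[:, h * dh : (h + 1) * dh]
            brute = np.sqrt(sum(x * x for x in block.ravel()))
            assert abs(row["l2_norm"] - brute) < 1e-9
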