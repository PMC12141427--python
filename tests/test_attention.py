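import math

import numpy as np
import pytest

from esa.attention import (MAB, MLP, PMA, SAB, AttentionParams, LayerNorm,
                           MultiHeadAttention, masked_sdpa, pool_seeds)
from esa.autograd import Parameter, Tensor, no_grad
from esa.masking import ADDITIVE_DISALLOWED


def params(d=8, h=2, **kw):
    return AttentionParams(hidden_dim=d, num_heads=h, **kw)


class TestMaskedSdpa:
    def test_diagonal_only_mask_returns_values(self, rng):
        L, dk = 5, 4
        q = Tensor(rng.normal(size=(L, dk)))
        k = Tensor(rng.normal(size=(L, dk)))
        v = Tensor(rng.normal(size=(L, dk)))
        m = np.full((L, L), ADDITIVE_DISALLOWED)
        np.fill_diagonal(m, 0.0)
        out = masked_sdpa(q, k, v, m)
        np.testing.assert_allclose(out.data, v.data, atol=1e-12)

    def test_zero_query_uniform_mean(self, rng):
        L, dk = 6, 3
        q = Tensor(np.zeros((L, dk)))
        k = Tensor(rng.normal(size=(L, dk)))
        v = Tensor(rng.normal(size=(L, dk)))
        out = masked_sdpa(q, k, v, None)
        np.testing.assert_allclose(out.data,
                                   np.tile(v.data.mean(0), (L, 1)), atol=1e-12)

    def test_scalar_loop_oracle(self, rng):
        q = Tensor(rng.normal(size=(2, 2)))
        k = Tensor(rng.normal(size=(2, 2)))
        v = Tensor(rng.normal(size=(2, 2)))
        m = np.array([[0.0, -1.0], [0.5, 0.0]])
        out = masked_sdpa(q, k, v, m).data
        expected = np.zeros((2, 2))
        for i in range(2):
            scores = [q.data[i] @ k.data[j] / math.sqrt(2) + m[i, j]
                      for j in range(2)]
            mx = max(scores)
            w = [math.exp(s - mx) for s in scores]
            z = sum(w)
            for j in range(2):
                expected[i] += (w[j] / z) * v.data[j]
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            masked_sdpa(Tensor(rng.normal(size=(3, 4))),
                        Tensor(rng.normal(size=(3, 5))),
                        Tensor(rng.normal(size=(3, 5))), None)


class TestMultiHead:
    def test_single_head_is_projected_sdpa(self, rng):
        p = params(d=6, h=1)
        mha = MultiHeadAttention(p, rng)
        x = Tensor(rng.normal(size=(1, 4, 6)))
        out = mha(x, x).data
        with no_grad():
            q = mha.w_q(x).data[0]
            k = mha.w_k(x).data[0]
            v = mha.w_v(x).data[0]
            inner = masked_sdpa(Tensor(q), Tensor(k), Tensor(v), None)
            expected = mha.w_o(Tensor(inner.data[None])).data
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_key_permutation_invariance(self, rng):
        p = params()
        mha = MultiHeadAttention(p, rng)
        x_q = Tensor(rng.normal(size=(1, 3, 8)))
        x_kv = rng.normal(size=(1, 5, 8))
        perm = rng.permutation(5)
        out1 = mha(x_q, Tensor(x_kv)).data
        out2 = mha(x_q, Tensor(x_kv[:, perm])).data
        np.testing.assert_allclose(out1, out2, atol=1e-10)

    def test_explicit_head_slicing_oracle(self, rng):
        p = params(d=4, h=2)
        mha = MultiHeadAttention(p, rng)
        x = rng.normal(size=(1, 3, 4))
        out = mha(Tensor(x), Tensor(x)).data
        with no_grad():
            q = mha.w_q(Tensor(x)).data[0]
            k = mha.w_k(Tensor(x)).data[0]
            v = mha.w_v(Tensor(x)).data[0]
            heads = []
            for hidx in range(2):
                sl = slice(2 * hidx, 2 * hidx + 2)
                heads.append(masked_sdpa(Tensor(q[:, sl]), Tensor(k[:, sl]),
                                         Tensor(v[:, sl]), None).data)
            concat = np.concatenate(heads, axis=-1)
            expected = mha.w_o(Tensor(concat[None])).data
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            AttentionParams(hidden_dim=6, num_heads=4)


class TestMab:
    def test_zeroed_projections_identity(self, rng):
        p = params()
        mab = MAB(p, rng)
        mab.attn.w_o.weight.data[:] = 0.0
        mab.attn.w_o.bias.data[:] = 0.0
        mab.mlp.fc2.weight.data[:] = 0.0
        mab.mlp.fc2.bias.data[:] = 0.0
        x = rng.normal(size=(2, 5, 8))
        out = mab(Tensor(x)).data
        # pre-norm residuals add the *normalized* input, so the block
        # degenerates to Norm(X), not X: both residual paths are identity
        with no_grad():
            expected = mab.norm1(Tensor(x)).data
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_output_shape(self, rng):
        p = params()
        mab = MAB(p, rng)
        for L in (1, 3, 7):
            x = Tensor(rng.normal(size=(2, L, 8)))
            assert mab(x).shape == (2, L, 8)

    def test_hand_unrolled_oracle(self, rng):
        p = params(d=4, h=1)
        mab = MAB(p, rng)
        x = rng.normal(size=(1, 3, 4))
        m = np.zeros((1, 1, 3, 3))
        out = mab(Tensor(x), m).data
        with no_grad():
            xb = mab.norm1(Tensor(x))
            h = xb.data + mab.attn(xb, xb, m).data
            expected = h + mab.mlp(mab.norm2(Tensor(h))).data
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_post_norm_placement(self, rng):
        p = params(norm_placement="post")
        mab = MAB(p, rng)
        x = rng.normal(size=(1, 4, 8))
        out = mab(Tensor(x)).data
        with no_grad():
            h = mab.norm1(Tensor(x) + mab.attn(Tensor(x), Tensor(x), None))
            expected = mab.norm2(h + mab.mlp(h)).data
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_gradients_flow(self, rng):
        p = params(d=4, h=2)
        mab = MAB(p, rng)
        x = Tensor(rng.normal(size=(1, 3, 4)))
        (mab(x) ** 2).sum().backward()
        for param in mab.parameters():
            assert param.grad is not None


class TestSab:
    def test_identical_to_mab_zero_mask(self, rng):
        p = params()
        sab = SAB(p, rng)
        x = rng.normal(size=(2, 4, 8))
        out_none = sab(Tensor(x)).data
        out_zero = MAB.__call__(sab, Tensor(x), np.zeros((2, 1, 4, 4))).data
        np.testing.assert_array_equal(out_none, out_zero)

    def test_equivalence_per_batch_random(self, rng):
        p = params(d=4, h=1)
        sab = SAB(p, rng)
        for _ in range(3):
            x = rng.normal(size=(3, 5, 4))
            a = sab(Tensor(x)).data
            b = MAB.__call__(sab, Tensor(x), np.zeros((3, 1, 5, 5))).data
            np.testing.assert_array_equal(a, b)

    def test_padding_mask_excludes_padded_keys(self, rng):
        from esa.masking import padding_mask, to_additive
        p = params(d=4, h=1)
        sab = SAB(p, rng)
        x = rng.normal(size=(1, 4, 4))
        pad = np.array([[True, True, True, False]])
        mask = to_additive(padding_mask(pad)).allowed[:, None]
        out_full = sab(Tensor(x), mask).data[:, :3]
        # changing the padded token must not alter real-token outputs
        x2 = x.copy()
        x2[0, 3] = 99.0
        out_mod = sab(Tensor(x2), mask).data[:, :3]
        np.testing.assert_allclose(out_full, out_mod, atol=1e-12)


class TestPma:
    def test_permutation_invariance(self, rng):
        pma = PMA(params(), k=4, p=1, rng=rng)
        z = rng.normal(size=(1, 6, 8))
        perm = rng.permutation(6)
        out1 = pma(Tensor(z)).data
        out2 = pma(Tensor(z[:, perm])).data
        np.testing.assert_allclose(out1, out2, atol=1e-5)

    def test_single_token_degenerate_softmax(self, rng):
        pma = PMA(params(), k=3, p=0, rng=rng)
        z = Tensor(rng.normal(size=(1, 1, 8)))
        record = []
        pma(z, record=record)
        np.testing.assert_allclose(record[0], 1.0)

    def test_k32_output_rows(self, rng):
        pma = PMA(params(), k=32, p=1, rng=rng)
        out = pma(Tensor(rng.normal(size=(2, 5, 8))))
        assert out.shape == (2, 32, 8)

    def test_bad_k(self, rng):
        with pytest.raises(ValueError):
            PMA(params(), k=0, p=0, rng=rng)


class TestPoolSeeds:
    def test_k1_identity(self, rng):
        x = rng.normal(size=(1, 8))
        np.testing.assert_allclose(pool_seeds(Tensor(x[None])).data, x)

    def test_mean_of_identical_rows(self):
        row = np.arange(4.0)
        x = Tensor(np.stack([row, row])[None])
        np.testing.assert_allclose(pool_seeds(x).data[0], row)

    def test_sum_vs_mean_factor_k(self, rng):
        x = Tensor(rng.normal(size=(1, 5, 8)))
        np.testing.assert_allclose(pool_seeds(x, "sum").data,
                                   5.0 * pool_seeds(x, "mean").data, atol=1e-12)


def test_gated_mlp_variant(rng):
    p = params(mlp_variant="gated")
    mlp = MLP(8, p, rng)
    x = Tensor(rng.normal(size=(2, 3, 8)))
    out = mlp(x)
    assert out.shape == (2, 3, 8)
    with no_grad():
        expected = mlp.fc2(mlp.fc1(x).silu() * mlp.gate(x)).data
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


def test_layernorm_statistics(rng):
    ln = LayerNorm(8)
    x = Tensor(rng.normal(size=(4, 8)) * 3 + 1)
    out = ln(x).data
    np.testing.assert_allclose(out.mean(-1), 0.0, atol=1e-10)
    np.testing.assert_allclose(out.std(-1), 1.0, atol=1e-2)
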