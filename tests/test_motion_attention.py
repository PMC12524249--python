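"""Motion-biased attention: residual, embedding, guidance matrix,
bias-augmented attention and the sequence-domain re-weighting."""

import numpy as np
import pytest

from dualview.errors import InvalidArgumentError
from dualview.motion_attention import (
    AttentionParams,
    biased_attention,
    build_motion_context,
    embed_motion,
    flatten_feature,
    motion_guidance,
    motion_residual,
    motion_weighted_attention,
    positional_encoding,
    random_params,
    sequence_motion_weighting,
    softmax_rows,
)


def plain_attention_reference(X, Wq, Wk, Wv):
    """Independent textbook scaled dot-product attention (loop form)."""
    Q, K, V = X @ Wq, X @ Wk, X @ Wv
    d_k = Wq.shape[1]
    out = np.zeros((X.shape[0], Wv.shape[1]))
    for i in range(X.shape[0]):
        scores = np.array([Q[i] @ K[j] / np.sqrt(d_k)
                           for j in range(X.shape[0])])
        w = np.exp(scores - scores.max())
        w /= w.sum()
        out[i] = sum(w[j] * V[j] for j in range(X.shape[0]))
    return out


class TestMotionResidual:
    def test_identical_frames_zero(self):
        F = np.random.default_rng(0).normal(size=(3, 4, 5))
        assert np.array_equal(motion_residual(F, F), np.zeros_like(F))

    def test_hand_example(self):
        Ft = np.array([[[1.0, -2.0]]])
        Ft_prev = np.array([[[-1.0, 1.0]]])
        assert np.array_equal(motion_residual(Ft, Ft_prev),
                              np.array([[[2.0, 3.0]]]))

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(1)
        Ft, Fp = rng.normal(size=(2, 3, 4)), rng.normal(size=(2, 3, 4))
        Dt = motion_residual(Ft, Fp)
        for c in range(2):
            for h in range(3):
                for w in range(4):
                    assert Dt[c, h, w] == abs(Ft[c, h, w] - Fp[c, h, w])

    def test_shape_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            motion_residual(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))


class TestEmbedMotion:
    def test_identity_weights_passthrough(self):
        Dt = np.abs(np.random.default_rng(2).normal(size=(3, 2, 2)))
        params = random_params(d_model=3, d_k=2, seed=0)
        params = AttentionParams(Wq=params.Wq, Wk=params.Wk, Wv=params.Wv,
                                 embed_weight=np.eye(3),
                                 embed_bias=np.zeros(3))
        Et, Et_flat = embed_motion(Dt, params)
        assert np.allclose(Et, Dt)
        assert Et_flat.shape == (4, 3)
        # row index is h·W + w (row-major)
        assert np.allclose(Et_flat[1], Dt[:, 0, 1])

    def test_relu_clips_negative_preactivation(self):
        Dt = np.ones((2, 2, 2))
        params = random_params(d_model=2, d_k=2, seed=0)
        params = AttentionParams(Wq=params.Wq, Wk=params.Wk, Wv=params.Wv,
                                 embed_weight=-np.eye(2),
                                 embed_bias=np.zeros(2))
        Et, _ = embed_motion(Dt, params)
        assert np.all(Et == 0.0)

    def test_matches_triple_loop(self):
        rng = np.random.default_rng(3)
        c, d, H, W = 4, 2, 3, 2
        Dt = np.abs(rng.normal(size=(c, H, W)))
        Wm, b = rng.normal(size=(d, c)), rng.normal(size=d)
        params = random_params(d_model=c, d_k=2, seed=0)
        params = AttentionParams(Wq=params.Wq, Wk=params.Wk, Wv=params.Wv,
                                 embed_weight=Wm, embed_bias=b)
        Et, _ = embed_motion(Dt, params)
        for dd in range(d):
            for h in range(H):
                for w in range(W):
                    pre = b[dd] + sum(Wm[dd, cc] * Dt[cc, h, w]
                                      for cc in range(c))
                    assert Et[dd, h, w] == pytest.approx(max(pre, 0.0))


class TestMotionGuidance:
    def test_single_position(self):
        assert np.array_equal(motion_guidance(np.array([[3.0, 1.0]])),
                              np.array([[1.0]]))

    def test_zero_embedding_uniform(self):
        Ms = motion_guidance(np.zeros((4, 3)))
        assert np.allclose(Ms, 0.25)

    def test_matches_brute_force_softmax(self):
        rng = np.random.default_rng(4)
        E = rng.normal(size=(6, 3))
        Ms = motion_guidance(E)
        G = E @ E.T
        for i in range(6):
            row = np.exp(G[i] - G[i].max())
            assert np.allclose(Ms[i], row / row.sum(), atol=1e-14)

    def test_rows_stochastic_entries_in_unit_interval(self):
        rng = np.random.default_rng(5)
        Ms = motion_guidance(rng.normal(size=(10, 4)))
        assert np.all(Ms > 0) and np.all(Ms < 1)
        assert np.allclose(Ms.sum(axis=1), 1.0, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            motion_guidance(np.array([[np.nan, 1.0]]))


class TestMotionWeightedAttention:
    def test_alpha_zero_equals_plain_attention_many_instances(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c, H, W = 4, 2, 3
            Ft = rng.normal(size=(c, H, W))
            Ms = motion_guidance(rng.normal(size=(H * W, 2)))
            params = random_params(d_model=c, d_k=3, d_v=2, alpha=0.0,
                                   seed=seed)
            out = motion_weighted_attention(Ft, Ms, params)
            ref = plain_attention_reference(flatten_feature(Ft), params.Wq,
                                            params.Wk, params.Wv)
            assert np.abs(out.reshape(2, -1).T - ref).max() < 1e-10

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        Ft = rng.normal(size=(3, 3, 3))
        Ms = motion_guidance(rng.normal(size=(9, 2)))
        params = random_params(d_model=3, d_k=2, alpha=2.0, seed=1)
        _, As = motion_weighted_attention(Ft, Ms, params, return_weights=True)
        assert np.abs(As.sum(axis=1) - 1.0).max() < 1e-12

    def test_large_alpha_concentrated_guidance_limit(self):
        # zero projections kill Q·Kᵀ; Ms concentrated on one column j
        # drives every output row to V[j] as α→∞
        N, c = 5, 3
        rng = np.random.default_rng(7)
        X = rng.normal(size=(N, c))
        j = 2
        Ms = np.full((N, N), 0.01 / (N - 1))
        Ms[:, j] = 0.99
        params = AttentionParams(Wq=np.zeros((c, 2)), Wk=np.zeros((c, 2)),
                                 Wv=rng.normal(size=(c, c)), alpha=500.0)
        Ys = biased_attention(X, Ms, params)
        V = X @ params.Wv
        assert np.abs(Ys - V[j]).max() < 1e-8

    def test_attention_mass_nondecreasing_in_alpha(self):
        # one-hot motion: a single spatial position differs between frames
        rng = np.random.default_rng(8)
        c, H, W = 4, 3, 3
        Ft_prev = rng.normal(size=(c, H, W))
        Ft = Ft_prev.copy()
        hot = (1, 2)
        Ft[:, hot[0], hot[1]] += 5.0
        col = hot[0] * W + hot[1]
        masses = []
        for alpha in [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0]:
            params = random_params(d_model=c, d_k=3, c_motion=c, d_embed=2,
                                   alpha=alpha, seed=42)
            ctx = build_motion_context(Ft, Ft_prev, params)
            assert np.argmax(ctx.Ms.sum(axis=0)) == col
            _, As = motion_weighted_attention(Ft, ctx.Ms, params,
                                              return_weights=True)
            masses.append(As[:, col].sum())
        assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        N, c = 6, 4
        X = rng.normal(size=(N, c))
        Ms = motion_guidance(rng.normal(size=(N, 3)))
        params = random_params(d_model=c, d_k=3, alpha=1.5, seed=2)
        perm = rng.permutation(N)
        out = biased_attention(X, Ms, params)
        out_perm = biased_attention(X[perm], Ms[np.ix_(perm, perm)], params)
        assert np.allclose(out_perm, out[perm], atol=1e-12)

    def test_full_chain_matches_brute_force(self):
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            c, d, H, W = 4, 2, 2, 3
            N = H * W
            Ft_prev = rng.normal(size=(c, H, W))
            Ft = rng.normal(size=(c, H, W))
            params = random_params(d_model=c, d_k=3, d_v=2, c_motion=c,
                                   d_embed=d, alpha=1.3, seed=seed)
            Ft_prime = motion_weighted_attention(
                Ft, build_motion_context(Ft, Ft_prev, params).Ms, params)

            # brute-force re-derivation with explicit loops
            Dt = np.abs(Ft - Ft_prev)
            Et = np.maximum(
                np.einsum("dc,chw->dhw", params.embed_weight, Dt)
                + params.embed_bias[:, None, None], 0.0)
            Ef = np.array([[Et[k, h, w] for k in range(d)]
                           for h in range(H) for w in range(W)])
            G = Ef @ Ef.T
            Ms = np.array([np.exp(G[i] - G[i].max())
                           / np.exp(G[i] - G[i].max()).sum()
                           for i in range(N)])
            X = np.array([[Ft[k, h, w] for k in range(c)]
                          for h in range(H) for w in range(W)])
            S = (X @ params.Wq) @ (X @ params.Wk).T / np.sqrt(3) \
                + 1.3 * Ms
            As = np.array([np.exp(S[i] - S[i].max())
                           / np.exp(S[i] - S[i].max()).sum()
                           for i in range(N)])
            Ys = As @ (X @ params.Wv)
            expected = Ys.T.reshape(2, H, W)
            assert np.abs(Ft_prime - expected).max() < 1e-10

    def test_shape_mismatch_rejected(self):
        params = random_params(d_model=3, d_k=2, seed=0)
        with pytest.raises(InvalidArgumentError):
            motion_weighted_attention(np.zeros((3, 2, 2)), np.eye(5), params)


class TestSequenceMotionWeighting:
    def test_single_element_sequence_is_value_projection(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(1, 4))
        params = random_params(d_model=4, d_k=2, alpha=3.0, seed=3)
        out = sequence_motion_weighting(x, np.array([[1.0]]), params)
        assert np.allclose(out, x @ params.Wv, atol=1e-12)

    def test_alpha_zero_is_baseline_attention(self):
        rng = np.random.default_rng(11)
        L, c = 7, 4
        seq = rng.normal(size=(L, c)) + positional_encoding(L, c)
        Ms = motion_guidance(rng.normal(size=(L, 2)))
        params = random_params(d_model=c, d_k=3, alpha=0.0, seed=4)
        out = sequence_motion_weighting(seq, Ms, params)
        ref = plain_attention_reference(seq, params.Wq, params.Wk, params.Wv)
        assert np.abs(out - ref).max() < 1e-10

    def test_random_case_matches_matrix_oracle(self):
        rng = np.random.default_rng(12)
        L, c = 5, 3
        seq = rng.normal(size=(L, c))
        Ms = motion_guidance(rng.normal(size=(L, 2)))
        params = random_params(d_model=c, d_k=2, alpha=0.7, seed=5)
        out = sequence_motion_weighting(seq, Ms, params)
        S = (seq @ params.Wq) @ (seq @ params.Wk).T / np.sqrt(2) + 0.7 * Ms
        expected = softmax_rows(S) @ (seq @ params.Wv)
        assert np.allclose(out, expected, atol=1e-12)

    def test_length_mismatch(self):
        params = random_params(d_model=3, d_k=2, seed=0)
        with pytest.raises(InvalidArgumentError):
            sequence_motion_weighting(np.zeros((4, 3)), np.eye(5), params)


def test_positional_encoding_shape_and_range():
    pe = positional_encoding(10, 6)
    assert pe.shape == (10, 6)
    assert np.all(np.abs(pe) <= 1.0)
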