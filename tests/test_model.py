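"""Layer semantics checked against literal per-node / per-pair loop oracles."""

import numpy as np
import pytest

from mvlda import (Config, bilinear_decode, build_similarity_bundle,
                   build_views, concat_embeddings, encode_view, gat_layer,
                   gat_scores, gcn_layer, init_params)
from mvlda.model import forward_scores


# -- independent loop oracles ---------------------------------------------

def gcn_oracle(Ahat, X, Wc, B):
    n, fin = X.shape
    fout = Wc.shape[1]
    out = np.zeros((n, fout))
    for i in range(n):
        agg = np.zeros(fin)
        for j in range(n):
            agg += Ahat[i, j] * X[j]
        out[i] = np.maximum(agg @ Wc + B[0], 0.0)
    return out


def gat_scores_oracle(H, Wt, b, mask):
    n = H.shape[0]
    e = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(n):
            if mask[i, j]:
                e[i, j] = (Wt @ H[j]) @ np.tanh(Wt @ H[i] + b[0])
    att = np.zeros((n, n))
    for i in range(n):
        ex = np.exp(e[i] - e[i][np.isfinite(e[i])].max())
        ex[~np.isfinite(e[i])] = 0.0
        att[i] = ex / ex.sum()
    return att


def gat_layer_oracle(H, att):
    n = H.shape[0]
    out = np.zeros_like(H)
    for i in range(n):
        agg = np.zeros(H.shape[1])
        for j in range(n):
            agg += att[i, j] * H[j]
        out[i] = np.maximum(agg, 0.0)
    return out


def bilinear_oracle(Yl, Yd, Wl, Wd):
    out = np.zeros((Yl.shape[0], Yd.shape[0]))
    for i in range(Yl.shape[0]):
        for j in range(Yd.shape[0]):
            out[i, j] = (Yl[i] @ Wl) @ (Yd[j] @ Wd)
    return out


def random_instance(rng, n=None):
    n = n or int(rng.integers(3, 11))
    A = (rng.random((n, n)) < 0.4).astype(float)
    A = np.maximum(A, A.T)
    mask = (A + np.eye(n)) > 0
    H = rng.standard_normal((n, 4))
    return A, mask, H


class TestGcnLayer:
    def test_uniform_propagation_hand_computed(self):
        Ahat = np.full((2, 2), 0.5)
        out = gcn_layer(Ahat, np.eye(2), np.eye(2), np.zeros((1, 2)))
        np.testing.assert_allclose(out, 0.5)

    def test_identity_propagation_preserves_nonnegative_features(self, rng):
        X = np.abs(rng.standard_normal((5, 3)))
        out = gcn_layer(np.eye(5), X, np.eye(3), np.zeros((1, 3)))
        np.testing.assert_allclose(out, X)

    def test_nonpositive_preactivation_gives_zeros(self):
        out = gcn_layer(np.eye(3), np.ones((3, 2)), -np.ones((2, 2)),
                        np.zeros((1, 2)))
        np.testing.assert_array_equal(out, 0.0)

    def test_non_finite_input_rejected(self):
        X = np.ones((2, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            gcn_layer(np.eye(2), X, np.eye(2), np.zeros((1, 2)))


class TestGatScores:
    def test_single_neighbor_gets_full_attention(self, rng):
        H = rng.standard_normal((2, 3))
        att = gat_scores(H, np.eye(3), np.zeros((1, 3)),
                         np.array([[True, False], [False, True]]))
        np.testing.assert_allclose(att, np.eye(2))

    def test_identical_neighbors_share_attention_equally(self):
        H = np.ones((2, 3))
        att = gat_scores(H, np.eye(3), np.zeros((1, 3)),
                         np.ones((2, 2), dtype=bool))
        np.testing.assert_allclose(att, 0.5)

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            A, mask, H = random_instance(rng)
            att = gat_scores(H, rng.standard_normal((4, 4)),
                             rng.standard_normal((1, 4)), mask)
            np.testing.assert_allclose(att.sum(axis=1), 1.0, atol=1e-8)

    def test_matches_per_pair_loop_oracle(self, rng):
        A, mask, H = random_instance(rng, n=5)
        Wt = rng.standard_normal((4, 4))
        b = rng.standard_normal((1, 4))
        np.testing.assert_allclose(gat_scores(H, Wt, b, mask),
                                   gat_scores_oracle(H, Wt, b, mask),
                                   atol=1e-10)


class TestGatLayer:
    def test_identity_attention_is_relu(self, rng):
        H = rng.standard_normal((4, 3))
        np.testing.assert_allclose(gat_layer(H, np.eye(4)),
                                   np.maximum(H, 0.0))

    def test_even_attention_averages_rows(self):
        H = np.array([[2.0, 0.0], [0.0, 4.0]])
        out = gat_layer(H, np.full((2, 2), 0.5))
        np.testing.assert_allclose(out, [[1.0, 2.0], [1.0, 2.0]])

    def test_equal_rows_stay_equal(self, rng):
        H = np.tile(rng.standard_normal(3), (5, 1))
        att = np.full((5, 5), 0.2)
        out = gat_layer(H, att)
        assert np.ptp(out, axis=0).max() == pytest.approx(0.0)


class TestEncodeView:
    def _params(self, rng, d_in, hid=6, lat=3):
        lim = 0.3
        return {
            "Wc1": rng.uniform(-lim, lim, (d_in, hid)),
            "B1": np.zeros((1, hid)),
            "Wt": rng.uniform(-lim, lim, (hid, hid)),
            "bt": np.zeros((1, hid)),
            "Wc2": rng.uniform(-lim, lim, (hid, lat)),
            "B2": np.zeros((1, lat)),
        }

    def test_matches_layer_by_layer_loop_composition(self, rng):
        from mvlda.networks import normalize_adjacency
        A, mask, _ = random_instance(rng, n=7)
        Ahat = normalize_adjacency(A)
        X0 = A + np.eye(7)
        vp = self._params(rng, 7)
        got = encode_view(Ahat, X0, vp, mask)
        H1 = gcn_oracle(Ahat, X0, vp["Wc1"], vp["B1"])
        att = gat_scores_oracle(H1, vp["Wt"], vp["bt"], mask)
        H2 = gat_layer_oracle(H1, att)
        expect = gcn_oracle(Ahat, H2, vp["Wc2"], vp["B2"])
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_keep_slices_select_entity_rows(self, rng):
        from mvlda.networks import normalize_adjacency
        A, mask, _ = random_instance(rng, n=8)
        Ahat = normalize_adjacency(A)
        vp = self._params(rng, 8)
        full = encode_view(Ahat, A + np.eye(8), vp, mask)
        part = encode_view(Ahat, A + np.eye(8), vp, mask,
                           keep=((0, 3), (5, 8)))
        np.testing.assert_allclose(part, np.vstack([full[0:3], full[5:8]]))

    def test_permutation_equivariance(self, rng):
        from mvlda.networks import normalize_adjacency
        A, mask, _ = random_instance(rng, n=6)
        X0 = A + np.eye(6)
        vp = self._params(rng, 6)
        perm = rng.permutation(6)
        P = np.eye(6)[perm]
        base = encode_view(normalize_adjacency(A), X0, vp, mask)
        permuted = encode_view(normalize_adjacency(P @ A @ P.T),
                               P @ X0 @ P.T, self._params_permuted(vp, perm),
                               (P @ mask @ P.T).astype(bool))
        np.testing.assert_allclose(permuted, P @ base, atol=1e-8)

    @staticmethod
    def _params_permuted(vp, perm):
        # input features are themselves node-indexed, so Wc1's rows permute
        out = dict(vp)
        out["Wc1"] = vp["Wc1"][perm]
        return out


class TestConcatAndDecode:
    def test_concat_widths_and_splits(self, rng):
        H1 = rng.standard_normal((7, 4))
        H2 = rng.standard_normal((7, 4))
        Y, Yl, Yd = concat_embeddings(H1, H2, nl=3)
        assert Y.shape == (7, 8)
        np.testing.assert_array_equal(Y[:, :4], H1)
        assert Yl.shape == (3, 8) and Yd.shape == (4, 8)

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="row mismatch"):
            concat_embeddings(np.zeros((3, 2)), np.zeros((4, 2)), nl=2)

    def test_unit_vectors_score_one(self):
        Yl = np.eye(1, 3)
        Yd = np.eye(1, 3)
        assert bilinear_decode(Yl, Yd, np.eye(3), np.eye(3))[0, 0] == 1.0

    def test_zero_disease_embeddings_give_zero_scores(self, rng):
        s = bilinear_decode(rng.standard_normal((4, 3)), np.zeros((5, 3)),
                            np.eye(3), np.eye(3))
        np.testing.assert_array_equal(s, 0.0)

    def test_matches_per_pair_loop_oracle(self, rng):
        Yl = rng.standard_normal((4, 6))
        Yd = rng.standard_normal((5, 6))
        Wl = rng.standard_normal((6, 2))
        Wd = rng.standard_normal((6, 2))
        np.testing.assert_allclose(bilinear_decode(Yl, Yd, Wl, Wd),
                                   bilinear_oracle(Yl, Yd, Wl, Wd),
                                   atol=1e-10)

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="width"):
            bilinear_decode(np.zeros((2, 3)), np.zeros((2, 3)),
                            np.zeros((4, 2)), np.zeros((3, 2)))


def test_forward_scores_shape_and_finiteness(tiny_dataset, fast_config, rng):
    ds, _ = tiny_dataset
    bundle = build_similarity_bundle(ds, fast_config)
    views = build_views(bundle, ds.LD, ds.LM)
    params = init_params(fast_config, views.X1.shape[1], views.F1.shape[1],
                         rng)
    scores = forward_scores(views, params).value
    assert scores.shape == (ds.nl, ds.nd)
    assert np.isfinite(scores).all()
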