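import numpy as np
import pytest
from sklearn.cluster import SpectralClustering
from sklearn.metrics import adjusted_rand_score

from mrcps.fusion import (
    MatrixFusion,
    SnfConfig,
    geometric_fusion,
    snf_fuse,
    snf_local,
    snf_normalize,
)
from mrcps.io import SimilarityMatrix


def sm(W, kind="kernel"):
    W = np.asarray(W, dtype=float)
    return SimilarityMatrix([f"p{i}" for i in range(W.shape[0])], W, kind=kind)


def random_similarity(rng, n):
    A = rng.uniform(0.05, 1.0, (n, n))
    W = (A + A.T) / 2
    np.fill_diagonal(W, 1.0)
    return W


class TestGeometricFusion:
    def test_idempotent_on_equal_inputs(self, rng):
        W = random_similarity(rng, 6)
        out = geometric_fusion(sm(W), sm(W))
        assert np.abs(out.W - W).max() < 1e-12

    def test_zero_propagates(self, rng):
        W1 = random_similarity(rng, 5)
        W2 = random_similarity(rng, 5)
        W1[0, 3] = W1[3, 0] = 0.0
        out = geometric_fusion(sm(W1), sm(W2))
        assert out.W[0, 3] == 0.0

    def test_hand_value(self):
        W1 = np.array([[1.0, 0.25], [0.25, 1.0]])
        W2 = np.array([[1.0, 0.81], [0.81, 1.0]])
        out = geometric_fusion(sm(W1), sm(W2))
        assert out.W[0, 1] == pytest.approx(0.45, abs=1e-12)

    def test_requires_unit_interval(self):
        with pytest.raises(ValueError):
            geometric_fusion(sm(np.array([[1.0, 2.0], [2.0, 1.0]])),
                             sm(np.array([[1.0, 0.5], [0.5, 1.0]])))


class TestSnfNormalize:
    def test_two_sample_closed_form(self):
        out = snf_normalize(np.array([[1.0, 0.3], [0.3, 1.0]]))
        assert np.allclose(out, [[0.5, 0.5], [0.5, 0.5]], atol=1e-12)

    def test_rows_sum_to_one_and_scale_invariance(self, rng):
        W = random_similarity(rng, 7)
        out = snf_normalize(W)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(out, snf_normalize(3.7 * W), atol=1e-12)

    def test_zero_row_sum_names_sample(self):
        W = np.eye(3)
        with pytest.raises(ValueError, match="sample index 0"):
            snf_normalize(W)


class TestSnfLocal:
    def test_full_neighborhood_keeps_all_offdiagonal(self, rng):
        W = random_similarity(rng, 6)
        S = snf_local(W, K=5)
        off = ~np.eye(6, dtype=bool)
        assert (S[off] > 0).all()
        assert (np.diag(S) == 0).all()

    def test_k1_chain_keeps_argmax_neighbor(self):
        W = np.array([[1.0, 0.9, 0.1],
                      [0.9, 1.0, 0.1],
                      [0.1, 0.1, 1.0]])
        S = snf_local(W, K=1)
        assert S[0, 1] == 0.5 and S[0, 2] == 0.0
        assert S[2, 0] == 0.5  # tie at 0.1 broken toward the earlier sample
        assert np.count_nonzero(S, axis=1).tolist() == [1, 1, 1]

    def test_nonzero_rows_sum_to_half(self, rng):
        W = random_similarity(rng, 9)
        S = snf_local(W, K=3)
        assert np.allclose(S.sum(axis=1), 0.5, atol=1e-12)


def snf_oracle(W1, W2, K, iters):
    """Plain-python re-statement of the cross-diffusion recursion."""
    def normalize(W):
        n = W.shape[0]
        P = np.zeros_like(W)
        for i in range(n):
            rs = sum(W[i, k] for k in range(n) if k != i)
            for j in range(n):
                P[i, j] = 0.5 if i == j else W[i, j] / (2 * rs)
        return P

    def local(W, K):
        n = W.shape[0]
        S = np.zeros_like(W)
        for i in range(n):
            order = sorted((j for j in range(n) if j != i),
                           key=lambda j: (-W[i, j], j))[:K]
            denom = sum(W[i, j] for j in order)
            for j in order:
                S[i, j] = W[i, j] / (2 * denom)
        return S

    P1, P2 = normalize(W1), normalize(W2)
    S1, S2 = local(W1, K), local(W2, K)
    for _ in range(iters):
        P1n = S1 @ P2 @ S1.T
        P2n = S2 @ P1 @ S2.T
        P1 = normalize((P1n + P1n.T) / 2)
        P2 = normalize((P2n + P2n.T) / 2)
    out = (P1 + P2) / 2
    return (out + out.T) / 2


class TestSnfFuse:
    def test_two_sample_fixed_point(self):
        W = np.array([[1.0, 0.4], [0.4, 1.0]])
        out = snf_fuse(sm(W), sm(W), SnfConfig(K=1, iters=5))
        assert np.allclose(out.W, [[0.5, 0.5], [0.5, 0.5]], atol=1e-9)

    def test_matches_brute_force_oracle_on_4x4(self, rng):
        W1 = random_similarity(rng, 4)
        W2 = random_similarity(rng, 4)
        out = snf_fuse(sm(W1), sm(W2), SnfConfig(K=2, iters=7))
        expect = snf_oracle(W1, W2, K=2, iters=7)
        assert np.abs(out.W - expect).max() < 1e-12

    def test_contract_symmetric_nonnegative_normalizable(self, rng):
        W1, W2 = random_similarity(rng, 10), random_similarity(rng, 10)
        out = snf_fuse(sm(W1), sm(W2), SnfConfig(K=4, iters=20))
        assert np.abs(out.W - out.W.T).max() < 1e-12
        assert (out.W >= 0).all()
        assert np.allclose(snf_normalize(out.W).sum(axis=1), 1.0, atol=1e-9)

    def test_permutation_equivariance(self, rng):
        n = 8
        W1, W2 = random_similarity(rng, n), random_similarity(rng, n)
        perm = rng.permutation(n)
        out = snf_fuse(sm(W1), sm(W2), SnfConfig(K=3, iters=10)).W
        out_p = snf_fuse(sm(W1[np.ix_(perm, perm)]), sm(W2[np.ix_(perm, perm)]),
                         SnfConfig(K=3, iters=10)).W
        assert np.abs(out[np.ix_(perm, perm)] - out_p).max() < 1e-10

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            snf_fuse(sm(random_similarity(rng, 4)), sm(random_similarity(rng, 5)))


def test_fused_matrix_clusters_at_least_as_well_as_single_platforms(rng):
    """Both platforms carry the same 2-subgroup signal plus independent noise;
    spectral clustering of the SNF-fused matrix should not lose accuracy."""
    n = 60
    truth = np.repeat([0, 1], n // 2)

    def platform():
        x = truth[:, None] * 3.0 + rng.normal(0, 1.0, (n, 3))
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
        W = np.exp(-d2 / d2.mean())
        np.fill_diagonal(W, 1.0)
        return W

    W1, W2 = platform(), platform()
    fused = snf_fuse(sm(W1), sm(W2), SnfConfig(K=10, iters=20)).W

    def ari(W):
        labels = SpectralClustering(2, affinity="precomputed",
                                    random_state=0).fit_predict(W)
        return adjusted_rand_score(truth, labels)

    assert ari(fused) >= max(ari(W1), ari(W2)) - 0.05


def test_estimator_dispatch(rng):
    W = random_similarity(rng, 6)
    geo = MatrixFusion(method="geometric").fit_transform((sm(W), sm(W)))
    assert geo.kind == "fused_geometric"
    snf = MatrixFusion(method="snf", K=2, iters=3).fit_transform((sm(W), sm(W)))
    assert snf.kind == "fused_snf"
    with pytest.raises(ValueError):
        MatrixFusion(method="nope").fit((sm(W), sm(W)))
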