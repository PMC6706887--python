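import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import normalized_mutual_info_score

from mrcps.consensus import (
    ConsensusProblem,
    ConsensusStratifier,
    categorical_distance,
    connectivity,
    frobenius_objective,
    nmi,
    optimize_partition,
    select_k,
    weighted_consensus,
)
from mrcps.io import Partition, SimilarityMatrix


def part(labels):
    labels = np.asarray(labels)
    return Partition([f"p{i}" for i in range(len(labels))], labels)


def ones_w(n):
    return SimilarityMatrix([f"p{i}" for i in range(n)], np.ones((n, n)))


def random_problem(rng, n, n_parts=2, max_labels=3):
    A = rng.uniform(size=(n, n))
    W = (A + A.T) / 2
    np.fill_diagonal(W, 1.0)
    ids = [f"p{i}" for i in range(n)]
    parts = [Partition(ids, rng.integers(0, max_labels, n)) for _ in range(n_parts)]
    return ConsensusProblem(parts, SimilarityMatrix(ids, W), seed=int(rng.integers(1 << 16)))


class TestCategoricalDistance:
    def test_identity_and_hand_case(self):
        a, b = part([1, 1, 2]), part([1, 2, 2])
        assert categorical_distance(a, a) == 0
        assert categorical_distance(a, b) == 2  # pairs (1,2) and (2,3) disagree

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(20):
            a = part(rng.integers(0, 3, 8))
            b = part(rng.integers(0, 3, 8))
            c = part(rng.integers(0, 3, 8))
            assert categorical_distance(a, b) == categorical_distance(b, a)
            assert (categorical_distance(a, c)
                    <= categorical_distance(a, b) + categorical_distance(b, c))

    def test_integer_valued(self, rng):
        a, b = part(rng.integers(0, 4, 10)), part(rng.integers(0, 4, 10))
        assert categorical_distance(a, b) == int(categorical_distance(a, b))


class TestWeightedConsensus:
    def test_all_ones_weight_reduces_to_average_connectivity(self):
        ps = [part([0, 0, 1]), part([0, 1, 1])]
        out = weighted_consensus(ps, ones_w(3))
        expect = (connectivity(ps[0]) + connectivity(ps[1])) / 2
        assert np.allclose(out, expect, atol=1e-12)

    def test_single_partition_is_weighted_connectivity(self, rng):
        W = ones_w(3).W * 0.25
        np.fill_diagonal(W, 1.0)
        sw = SimilarityMatrix([f"p{i}" for i in range(3)], W)
        out = weighted_consensus([part([0, 1, 1])], sw)
        assert np.allclose(out, connectivity(part([0, 1, 1])) * np.sqrt(sw.W), atol=1e-12)

    def test_three_sample_hand_case(self):
        W = np.array([[1.0, 0.25, 0.0],
                      [0.25, 1.0, 0.64],
                      [0.0, 0.64, 1.0]])
        sw = SimilarityMatrix(["p0", "p1", "p2"], W)
        ps = [part([0, 0, 1]), part([0, 1, 1])]
        out = weighted_consensus(ps, sw)
        # entry (0,1): partitions contribute (1 + 0)/2 * sqrt(0.25) = 0.25
        assert out[0, 1] == pytest.approx(0.25, abs=1e-12)
        # entry (1,2): (0 + 1)/2 * sqrt(0.64) = 0.4
        assert out[1, 2] == pytest.approx(0.4, abs=1e-12)
        # diagonal: sqrt(1) = 1
        assert np.allclose(np.diag(out), 1.0)


class TestOptimizePartition:
    def test_clean_blocks_attain_zero_objective(self):
        truth = part([0, 0, 1, 1, 2, 2])
        prob = ConsensusProblem([truth], ones_w(6), seed=0)
        res = optimize_partition(prob, k=3)
        assert res.objective == pytest.approx(0.0, abs=1e-12)
        assert categorical_distance(res.partition, truth) == 0

    def test_spectral_matches_exhaustive_within_tolerance(self, rng):
        worst = 1.0
        for _ in range(20):
            prob = random_problem(rng, 7)
            k = int(rng.integers(2, 5))
            ex = optimize_partition(prob, k, exhaustive=True)
            sp = optimize_partition(prob, k)
            assert sp.objective >= ex.objective - 1e-9
            if ex.objective > 0:
                worst = max(worst, sp.objective / ex.objective)
        assert worst <= 1.05

    def test_weight_arbitrates_conflicting_partitions(self):
        # two clinical partitions disagree; W carries affinity only within
        # the blocks of the first -> consensus follows the W-favored blocks
        p1 = part([0, 0, 0, 1, 1, 1])
        p2 = part([0, 0, 1, 1, 0, 1])
        W = np.full((6, 6), 1e-6)
        blocks = connectivity(p1).astype(bool)
        W[blocks] = 1.0
        np.fill_diagonal(W, 1.0)
        prob = ConsensusProblem([p1, p2],
                                SimilarityMatrix([f"p{i}" for i in range(6)], W), seed=1)
        res = optimize_partition(prob, k=2, exhaustive=True)
        assert categorical_distance(res.partition, p1) == 0

    def test_consensus_never_worse_than_inputs(self, rng):
        for _ in range(10):
            prob = random_problem(rng, 12)
            s_tilde = weighted_consensus(prob.clinical_partitions, prob.W)
            sqrt_w = np.sqrt(prob.W.W)
            for k in (2, 3):
                res = optimize_partition(prob, k)
                for p in prob.clinical_partitions:
                    if p.k <= k:
                        assert res.objective <= frobenius_objective(
                            p.labels, s_tilde, sqrt_w) + 1e-9

    def test_k_out_of_range(self, rng):
        prob = random_problem(rng, 5)
        with pytest.raises(ValueError):
            optimize_partition(prob, k=6)


class TestNmi:
    def test_identical_balanced_partitions(self):
        assert nmi(part([0, 0, 1, 1]), part([0, 0, 1, 1])) == pytest.approx(1.0)

    def test_orthogonal_partitions_zero(self):
        assert nmi(part([1, 1, 2, 2]), part([1, 2, 1, 2])) == pytest.approx(0.0, abs=1e-12)

    def test_zero_entropy_guard(self):
        assert nmi(part([0, 0, 0]), part([0, 1, 2])) == 0.0

    def test_bounded_and_matches_sklearn(self, rng):
        for _ in range(200):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 4, 30)
            v = nmi(part(a), part(b))
            assert -1e-12 <= v <= 1 + 1e-12
            expect = normalized_mutual_info_score(a, b, average_method="geometric")
            assert v == pytest.approx(expect, abs=1e-9)

    def test_independent_labels_vanish_at_large_n(self, rng):
        base = rng.integers(0, 3, 500)
        vals = []
        for _ in range(100):
            shuffled = rng.permutation(base)
            vals.append(nmi(part(base), part(shuffled)))
        assert np.mean(vals) < 0.05


class TestSelectK:
    def test_identical_bases_recover_block_count(self):
        truth = part([0] * 4 + [1] * 4 + [2] * 4)
        prob = ConsensusProblem([truth, truth], ones_w(12),
                                k_range=(2, 3, 4, 5), seed=0)
        res = select_k(prob, base=[truth, truth])
        assert res.k == 3
        assert res.nmi_score == pytest.approx(2.0, abs=1e-9)

    def test_single_candidate_returned_regardless_of_score(self, rng):
        prob = random_problem(rng, 10)
        prob.k_range = (2,)
        res = select_k(prob, base=[prob.clinical_partitions[0]])
        assert res.k == 2 or res.partition.k <= 2

    def test_per_k_trace_recorded(self, rng):
        prob = random_problem(rng, 10)
        prob.k_range = (2, 3)
        res = select_k(prob, base=list(prob.clinical_partitions))
        assert set(res.per_k) == {2, 3}


def test_stratifier_estimator_surface(rng):
    prob = random_problem(rng, 12)
    est = ConsensusStratifier(k_range=(2, 3), seed=0)
    labels = est.fit_predict(prob.W, partitions=prob.clinical_partitions)
    assert len(labels) == 12
    assert est.k_ == len(np.unique(labels))
    assert est.objective_ >= 0
    assert est.get_params()["k_range"] == (2, 3)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    labels_a=st.lists(st.integers(0, 3), min_size=2, max_size=20),
    labels_b=st.lists(st.integers(0, 3), min_size=2, max_size=20),
)
def test_nmi_symmetry_and_bounds_property(labels_a, labels_b):
    """NMI is symmetric, bounded in [0, 1], and 1 on self-comparison for any
    non-degenerate labeling."""
    n = min(len(labels_a), len(labels_b))
    a, b = part(labels_a[:n]), part(labels_b[:n])
    v = nmi(a, b)
    assert 0.0 <= v <= 1.0
    assert v == pytest.approx(nmi(b, a), abs=1e-12)
    if a.k > 1:
        assert nmi(a, a) == pytest.approx(1.0, abs=1e-12)
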