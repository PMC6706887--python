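"""Molecular-regularized consensus stratification.

Clinical partitions (stage, risk) enter as 0/1 pairwise connectivity
matrices; the fused molecular similarity W down-weights clinical agreement
between molecularly dissimilar patients.  The consensus partition minimizes
the Frobenius discrepancy

    || S~L - S o sqrt(W) ||_F^2,      S~L = (1/L) sum_l S^l o sqrt(W),

over k-cluster partitions S (o = Hadamard product).  The optimizer uses a
spectral relaxation (top-k eigenvectors of S~L, row-normalized, K-means)
followed by greedy single-sample reassignment on the exact objective; for
n <= 9 an exhaustive enumeration mode certifies the global optimum.  The
cluster number is selected by maximizing the summed normalized mutual
information with the base clusterings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .io import Partition, SimilarityMatrix


@dataclass
class ConsensusProblem:
    clinical_partitions: list[Partition]
    W: SimilarityMatrix
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    seed: int = 0

    def __post_init__(self):
        if not self.clinical_partitions:
            raise ValueError("at least one clinical partition required")
        ids = list(self.W.sample_ids)
        for p in self.clinical_partitions:
            if list(p.sample_ids) != ids:
                raise ValueError("partitions and W must share sample ordering")


@dataclass
class ConsensusResult:
    partition: Partition
    objective: float
    k: int
    nmi_score: float = float("nan")
    weighted_consensus: np.ndarray = field(default=None, repr=False)
    per_k: dict = field(default_factory=dict)


def connectivity(p: Partition) -> np.ndarray:
    return p.connectivity()


def categorical_distance(p1: Partition, p2: Partition) -> float:
    """Symmetric-difference distance: number of sample pairs on which the
    two partitions disagree about co-membership."""
    if list(p1.sample_ids) != list(p2.sample_ids):
        raise ValueError("partitions cover different samples")
    d = p1.connectivity() - p2.connectivity()
    return float((d**2).sum() / 2.0)  # each unordered pair counted once


def weighted_consensus(ps: list[Partition], W: SimilarityMatrix) -> np.ndarray:
    """S~L = (1/L) sum_l S^l o sqrt(W)."""
    if not ps:
        raise ValueError("no partitions given")
    sw = np.sqrt(W.W)
    out = np.zeros_like(sw)
    for p in ps:
        out += p.connectivity() * sw
    return out / len(ps)


def frobenius_objective(labels: np.ndarray, s_tilde: np.ndarray, sqrt_w: np.ndarray) -> float:
    """Exact || S~L - S o sqrt(W) ||_F^2 for the partition given by labels."""
    S = (labels[:, None] == labels[None, :]).astype(float)
    diff = s_tilde - S * sqrt_w
    return float((diff**2).sum())


def _greedy_refine(labels: np.ndarray, k: int, s_tilde: np.ndarray,
                   sqrt_w: np.ndarray, max_passes: int = 20) -> np.ndarray:
    """Single-sample reassignment descent on the exact Frobenius objective."""
    labels = labels.copy()
    n = len(labels)
    a = s_tilde * sqrt_w          # cross term coefficients
    b = sqrt_w**2
    for _ in range(max_passes):
        improved = False
        for i in range(n):
            # contribution of row/col i: sum_{j != i} [(s~_ij - s_ij w_ij)^2] * 2
            # moving i to cluster c changes only terms with s_ij = 1(c_j == c)
            cur = labels[i]
            mask = np.arange(n) != i
            best_c, best_delta = cur, 0.0
            for c in range(k):
                if c == cur:
                    continue
                in_new = (labels == c) & mask
                in_old = (labels == cur) & mask
                # cost of edges i-j with s_ij = 1: (s~ - w)^2 = s~^2 - 2a + b; with s_ij=0: s~^2
                delta = 2.0 * ((b[i, in_new] - 2 * a[i, in_new]).sum()
                               - (b[i, in_old] - 2 * a[i, in_old]).sum())
                if delta < best_delta - 1e-12:
                    best_delta, best_c = delta, c
            if best_c != cur:
                labels[i] = best_c
                improved = True
        if not improved:
            break
    return labels


def optimize_partition(problem: ConsensusProblem, k: int,
                       exhaustive: bool = False, n_restarts: int = 50) -> ConsensusResult:
    """Minimize the Frobenius consensus objective over k-cluster partitions."""
    n = len(problem.W.sample_ids)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    sqrt_w = np.sqrt(problem.W.W)
    s_tilde = weighted_consensus(problem.clinical_partitions, problem.W)

    if exhaustive:
        if n > 9:
            raise ValueError("exhaustive mode is limited to n <= 9")
        best, best_obj = None, math.inf
        for labels in _partitions_into_k(n, k):
            obj = frobenius_objective(labels, s_tilde, sqrt_w)
            if obj < best_obj - 1e-15:
                best_obj, best = obj, labels
        labels = best
    else:
        inits = [_spectral_labels(s_tilde, k, problem.seed, n_restarts)]
        # clinical partitions are admissible starting points whenever they use <= k labels
        for p in problem.clinical_partitions:
            if p.k <= k:
                _, relab = np.unique(p.labels, return_inverse=True)
                inits.append(relab)
        # random restarts guard against local minima of the greedy descent; the
        # spectral relaxation is coarse on small problems, so restart harder there
        rng = np.random.default_rng(problem.seed + 7919 * k)
        n_random = 20 if n <= 30 else 2
        inits += [rng.integers(0, k, size=n) for _ in range(n_random)]
        labels, best_obj = None, math.inf
        for init in inits:
            cand = _greedy_refine(init, k, s_tilde, sqrt_w)
            obj = frobenius_objective(cand, s_tilde, sqrt_w)
            if obj < best_obj - 1e-15:
                best_obj, labels = obj, cand
        labels = _assign_orphans(labels, problem, k)
    obj = frobenius_objective(labels, s_tilde, sqrt_w)
    part = Partition(list(problem.W.sample_ids), labels)
    return ConsensusResult(partition=part, objective=obj, k=part.k,
                           weighted_consensus=s_tilde)


def _assign_orphans(labels: np.ndarray, problem: ConsensusProblem, k: int,
                    max_passes: int = 10) -> np.ndarray:
    """Deterministic placement of molecularly unconstrained sample groups.

    The Frobenius objective decomposes over connected components of the
    affinity graph, so the grouping of cluster fragments (component x cluster
    intersections) across components is a plateau: moving a fragment between
    clusters costs nothing whenever the move leaves every weighted pair term
    unchanged.  Among those free moves the objective cannot arbitrate, and
    the optimizer's choice would otherwise be an artifact of its
    initialization.  Fragments are therefore regrouped greedily to minimize
    the *unweighted* clinical-consensus discrepancy
    sum_{i<j} (mean_l S^l_ij - S_ij)^2 — the plain categorical consensus —
    accepting only moves that provably leave the weighted objective
    unchanged.  Iterated to a fixpoint; labels compacted at the end.
    """
    from scipy.sparse.csgraph import connected_components

    W = problem.W.W.copy()
    np.fill_diagonal(W, 0.0)
    if not (W > 0).any():
        _, labels = np.unique(labels, return_inverse=True)
        return labels
    labels = labels.copy()
    n = len(labels)
    sqrt_w = np.sqrt(W)
    s_tilde = weighted_consensus(problem.clinical_partitions, problem.W)
    np.fill_diagonal(s_tilde, 0.0)
    conns = [p.connectivity() for p in problem.clinical_partitions]
    mean_conn = sum(conns) / len(conns)

    _, comp = connected_components((W > 0).astype(np.int8), directed=False)

    def pair_cost(i_idx, j_mask, joined: bool) -> tuple[float, float]:
        """(weighted, clinical) cost of pairs between fragment and mask."""
        s = 1.0 if joined else 0.0
        wcost = ((s_tilde[np.ix_(i_idx, np.where(j_mask)[0])]
                  - s * sqrt_w[np.ix_(i_idx, np.where(j_mask)[0])]) ** 2).sum()
        ccost = ((mean_conn[np.ix_(i_idx, np.where(j_mask)[0])] - s) ** 2).sum()
        return wcost, ccost

    for _ in range(max_passes):
        moved = False
        frag_keys = sorted({(int(comp[i]), int(labels[i])) for i in range(n)})
        for comp_id, cl in frag_keys:
            frag = np.where((comp == comp_id) & (labels == cl))[0]
            if frag.size == 0:
                continue
            rest_own = (labels == cl)
            rest_own[frag] = False
            w_out, c_out = pair_cost(frag, rest_own, joined=True)
            w_out0, c_out0 = pair_cost(frag, rest_own, joined=False)
            best_c, best_gain = cl, 0.0
            for c in np.unique(labels):
                if c == cl:
                    continue
                target = labels == c
                # destination gate: a majority of the fragment-target pairs must be
                # clinically co-grouped (mean co-membership > 1/2).  Aggregate gain
                # alone would let a sliver of impure pairs merge two large molecular
                # blocks that the clinical consensus is otherwise indifferent about.
                cross = mean_conn[np.ix_(frag, np.where(target)[0])]
                if (cross > 0.5).mean() <= 0.5:
                    continue
                w_in0, c_in0 = pair_cost(frag, target, joined=False)
                w_in, c_in = pair_cost(frag, target, joined=True)
                dw = (w_out0 - w_out) + (w_in - w_in0)
                if abs(dw) > 1e-12:
                    continue  # the weighted objective forbids this move
                dc = (c_out0 - c_out) + (c_in - c_in0)
                if dc < best_gain - 1e-12:
                    best_c, best_gain = int(c), dc
            if best_c != cl:
                labels[frag] = best_c
                moved = True
        if not moved:
            break
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _spectral_labels(s_tilde: np.ndarray, k: int, seed: int, n_restarts: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(s_tilde)
    U = vecs[:, np.argsort(-vals)[:k]]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = U / norms
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(U)


def _partitions_into_k(n: int, k: int):
    """All partitions of n items into exactly k non-empty groups
    (restricted-growth strings)."""
    def rec(i, labels, used):
        if i == n:
            if used == k:
                yield np.array(labels)
            return
        if k - used > n - i:  # cannot reach k groups any more
            return
        for c in range(min(used + 1, k)):
            labels.append(c)
            yield from rec(i + 1, labels, used + (1 if c == used else 0))
            labels.pop()
    yield from rec(0, [], 0)


def nmi(p1: Partition, p2: Partition) -> float:
    """NMI = (H1 + H2 - Hjoint) / sqrt(H1 * H2), natural-log entropies;
    0 whenever either marginal entropy is 0."""
    if len(p1.labels) != len(p2.labels):
        raise ValueError("partitions cover different sample counts")
    n = len(p1.labels)
    _, c1 = np.unique(p1.labels, return_counts=True)
    _, c2 = np.unique(p2.labels, return_counts=True)
    joint = {}
    for a, b in zip(p1.labels, p2.labels):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    h1 = _entropy(c1 / n)
    h2 = _entropy(c2 / n)
    if h1 <= 0 or h2 <= 0:
        return 0.0
    hj = _entropy(np.array(list(joint.values())) / n)
    mi = h1 + h2 - hj
    return float(min(1.0, max(0.0, mi / math.sqrt(h1 * h2))))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi_sum(final: Partition, base: list[Partition]) -> float:
    """phi(NMI): summed NMI of the final partition against each base clustering."""
    return float(sum(nmi(b, final) for b in base))


def select_k(problem: ConsensusProblem, base: list[Partition],
             exhaustive: bool = False) -> ConsensusResult:
    """Optimize at every k in k_range, return the result maximizing phi(NMI).

    Ties break toward smaller k.
    """
    if not problem.k_range:
        raise ValueError("empty k_range")
    best = None
    trace = {}
    for k in sorted(problem.k_range):
        res = optimize_partition(problem, k, exhaustive=exhaustive)
        res.nmi_score = nmi_sum(res.partition, base)
        trace[k] = {"objective": res.objective, "nmi": res.nmi_score}
        if best is None or res.nmi_score > best.nmi_score + 1e-12:
            best = res
    best.per_k = trace
    return best


class ConsensusStratifier(BaseEstimator, ClusterMixin):
    """Consensus clusterer over clinical partitions regularized by molecular similarity.

    fit(X, partitions=...) takes the fused SimilarityMatrix as X and the
    clinical partitions (stage, risk, ...) as keyword data; fitted attributes
    are ``labels_``, ``k_``, ``objective_``, ``nmi_score_`` and ``per_k_``.
    ``base_partitions`` (default: the clinical partitions) are the clusterings
    against which the NMI model-selection score is computed; pass the
    molecular base clustering there to mirror the full workflow.
    """

    def __init__(self, k_range=(2, 3, 4, 5, 6, 7, 8), seed=0, exhaustive=False):
        self.k_range = k_range
        self.seed = seed
        self.exhaustive = exhaustive

    def fit(self, X: SimilarityMatrix, y=None, *, partitions, base_partitions=None):
        problem = ConsensusProblem(list(partitions), X,
                                   k_range=tuple(self.k_range), seed=self.seed)
        base = list(base_partitions) if base_partitions is not None else list(partitions)
        res = select_k(problem, base, exhaustive=self.exhaustive)
        self.result_ = res
        self.labels_ = res.partition.labels
        self.k_ = res.k
        self.objective_ = res.objective
        self.nmi_score_ = res.nmi_score
        self.per_k_ = res.per_k
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, **kwargs).labels_
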