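"""Fusion of the two platform similarity matrices.

Two routes: the elementwise geometric mean (which keeps affinity only where
both platforms agree on a shared cluster) and similarity network fusion
(SNF), an iterative cross-diffusion of the two normalized matrices through
their K-nearest-neighbor local-affinity graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io import SimilarityMatrix


@dataclass
class SnfConfig:
    K: int | None = None  # neighbor count; None = min(20, max(5, n // 10))
    iters: int = 20

    def __post_init__(self):
        if self.iters < 1:
            raise ValueError("iters must be >= 1")


def default_snf_K(n: int) -> int:
    return min(min(20, max(5, n // 10)), n - 1)


def geometric_fusion(w1: SimilarityMatrix, w2: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise geometric mean sqrt(W1 * W2); zero wherever either input is zero."""
    _check_pair(w1, w2)
    if w1.W.max() > 1 + 1e-9 or w2.W.max() > 1 + 1e-9:
        raise ValueError("geometric fusion expects entries in [0, 1]")
    W = np.sqrt(w1.W * w2.W)
    return SimilarityMatrix(list(w1.sample_ids), W, kind="fused_geometric")


def snf_normalize(W: np.ndarray) -> np.ndarray:
    """Full-information normalization: off-diagonal W_ij / (2 sum_{k != i} W_ik), diagonal 1/2."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rs = off.sum(axis=1)
    if (rs <= 0).any():
        bad = int(np.argmax(rs <= 0))
        raise ValueError(f"zero off-diagonal row sum at sample index {bad}")
    P = off / (2.0 * rs[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def snf_local(W: np.ndarray, K: int) -> np.ndarray:
    """KNN local-affinity kernel: row-restricted to the K largest neighbors.

    S_ij = W_ij / (2 sum_{k in N_i} W_ik) for j among i's K strongest
    neighbors (excluding i), 0 elsewhere including the diagonal; ties at the
    K-th neighbor break by sample order.  Nonzero rows sum to 1/2.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not 1 <= K <= n - 1:
        raise ValueError(f"K={K} out of range for n={n}")
    off = W.copy()
    np.fill_diagonal(off, -np.inf)
    S = np.zeros_like(W)
    for i in range(n):
        # stable sort on (-weight, index): ties at the K-th slot go to earlier samples
        order = np.lexsort((np.arange(n), -off[i]))
        nbr = order[:K]
        denom = W[i, nbr].sum()
        if denom > 0:
            S[i, nbr] = W[i, nbr] / (2.0 * denom)
    return S


def snf_fuse(w1: SimilarityMatrix, w2: SimilarityMatrix,
             cfg: SnfConfig | None = None) -> SimilarityMatrix:
    """Cross-diffuse the two similarity matrices and average.

    P^(1) <- S^(1) P^(2) S^(1)^T (and symmetrically), re-normalizing after
    every step; after ``iters`` steps the result is (P^(1) + P^(2)) / 2,
    symmetrized.
    """
    _check_pair(w1, w2)
    if cfg is None:
        cfg = SnfConfig()
    n = len(w1.sample_ids)
    K = default_snf_K(n) if cfg.K is None else cfg.K
    P1, P2 = snf_normalize(w1.W), snf_normalize(w2.W)
    S1, S2 = snf_local(w1.W, K), snf_local(w2.W, K)
    for _ in range(cfg.iters):
        P1n = S1 @ P2 @ S1.T
        P2n = S2 @ P1 @ S2.T
        P1 = snf_normalize((P1n + P1n.T) / 2.0)
        P2 = snf_normalize((P2n + P2n.T) / 2.0)
    W = (P1 + P2) / 2.0
    W = (W + W.T) / 2.0
    return SimilarityMatrix(list(w1.sample_ids), W, kind="fused_snf")


def _check_pair(w1: SimilarityMatrix, w2: SimilarityMatrix) -> None:
    if list(w1.sample_ids) != list(w2.sample_ids):
        raise ValueError("sample orderings differ between the two matrices")
    if w1.W.shape != w2.W.shape:
        raise ValueError("matrix dimension mismatch")


class MatrixFusion(BaseEstimator):
    """Estimator fusing exactly two platform similarity matrices."""

    def __init__(self, method="geometric", K=None, iters=20):
        self.method = method
        self.K = K
        self.iters = iters

    def fit(self, X, y=None):
        w1, w2 = X
        if self.method == "geometric":
            self.fused_ = geometric_fusion(w1, w2)
        elif self.method == "snf":
            self.fused_ = snf_fuse(w1, w2, SnfConfig(K=self.K, iters=self.iters))
        else:
            raise ValueError(f"unknown fusion method {self.method!r}")
        return self

    def fit_transform(self, X, y=None) -> SimilarityMatrix:
        return self.fit(X).fused_
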