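"""Weighted co-expression module mining (lmQCM).

The miner builds an absolute-Spearman gene-gene weight matrix, applies the
spectral-style degree normalization W'_ij = W_ij / sqrt(d_i d_j), seeds
candidate modules at locally maximal edges whose weight reaches gamma * w_max,
grows each seed greedily under an adaptive density rule, and merges modules
whose overlap ratio |A∩B| / min(|A|,|B|) exceeds beta.

Growth rule.  With current cluster C (|C| = n_c, density d(C) = mean pairwise
weight) the candidate vertex v maximizing its total weight w(v, C) to the
cluster is accepted while

    w(v, C) / n_c  >=  alpha_d * d(C),    alpha_d = 1 - 1 / (2 * lambda * (n_c + t)).

The rule is scale-free: the adaptive coefficient alpha_d tightens as the
module grows, while the comparison against the current density makes the
threshold track the weight scale of the network (raw or degree-normalized).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix, ModuleSet

logger = logging.getLogger(__name__)


@dataclass
class LmqcmParams:
    gamma: float = 0.80
    lambda_: float = 2.0
    t_density: float = 1.0
    beta: float = 0.4
    min_size: int = 10

    def __post_init__(self):
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.t_density < 0:
            raise ValueError("t_density must be >= 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")
        if self.min_size < 3:
            raise ValueError("min_size must be >= 3")


@dataclass
class WeightMatrix:
    gene_ids: list[str]
    W: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.gene_ids)
        if self.W.shape != (n, n):
            raise ValueError("weight matrix shape mismatch")
        if not np.allclose(self.W, self.W.T, atol=1e-12):
            raise ValueError("weight matrix not symmetric")
        if (self.W < 0).any():
            raise ValueError("negative edge weights")
        np.fill_diagonal(self.W, 0.0)


def spearman_weights(e: ExpressionMatrix) -> WeightMatrix:
    """|Spearman rho| between all gene pairs (average ranks for ties)."""
    x = e.values.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("Spearman weights require >= 3 samples")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(e.gene_ids, sd) if s == 0]
        raise ValueError(f"constant gene rows (remove upstream): {bad[:5]}")
    ranks = np.apply_along_axis(rankdata, 1, x)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    rho = (ranks @ ranks.T) / np.outer(norms, norms)
    W = np.abs(np.clip(rho, -1.0, 1.0))
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    return WeightMatrix(list(e.gene_ids), W)


def normalize_weights(w: WeightMatrix) -> WeightMatrix:
    """Spectral-style normalization W_ij / sqrt(d_i d_j); zero-degree rows stay zero."""
    d = w.W.sum(axis=1)
    isolated = d == 0
    if isolated.any():
        logger.warning("%d isolated genes produce zero rows", int(isolated.sum()))
    inv = np.zeros_like(d)
    inv[~isolated] = 1.0 / np.sqrt(d[~isolated])
    Wn = w.W * np.outer(inv, inv)
    return WeightMatrix(list(w.gene_ids), Wn)


def _grow_module(W: np.ndarray, seed: tuple[int, int], p: LmqcmParams) -> list[int]:
    """Greedy quasi-clique growth from a seed edge."""
    members = [seed[0], seed[1]]
    in_c = np.zeros(W.shape[0], dtype=bool)
    in_c[members] = True
    total = W[seed[0], seed[1]]          # sum of within-cluster edge weights
    conn = W[seed[0]] + W[seed[1]]       # each vertex's total weight into C
    while True:
        n_c = len(members)
        density = 2.0 * total / (n_c * (n_c - 1))
        alpha = 1.0 - 1.0 / (2.0 * p.lambda_ * (n_c + p.t_density))
        cand = np.where(~in_c)[0]
        if cand.size == 0:
            break
        gains = conn[cand]
        best = gains.max()
        if best <= 0 or best / n_c < alpha * density:
            break
        # tie-break: smallest gene index wins
        v = int(cand[np.nonzero(gains == best)[0][0]])
        members.append(v)
        in_c[v] = True
        total += best
        conn += W[v]
    return members


def seed_edges(w: WeightMatrix, gamma: float) -> list[tuple[int, int, float]]:
    """Candidate seed edges, descending weight order.

    An edge qualifies if its weight reaches gamma * w_max and is a local
    maximum: no adjacent edge of either endpoint is strictly heavier.
    """
    W = w.W
    n = W.shape[0]
    if n == 0 or not (W > 0).any():
        return []
    w_max = W.max()
    iu, ju = np.triu_indices(n, k=1)
    wts = W[iu, ju]
    keep = wts >= gamma * w_max
    iu, ju, wts = iu[keep], ju[keep], wts[keep]
    order = np.argsort(-wts, kind="stable")
    row_max = W.max(axis=1)
    out = []
    for e in order:
        i, j, wij = int(iu[e]), int(ju[e]), float(wts[e])
        if wij < row_max[i] or wij < row_max[j]:
            continue
        out.append((i, j, wij))
    return out


def mine_modules(w: WeightMatrix, p: LmqcmParams | None = None) -> ModuleSet:
    """Mine quasi-clique modules from a weight matrix."""
    if p is None:
        p = LmqcmParams()
    W = w.W
    raw = [_grow_module(W, (i, j), p) for i, j, _ in seed_edges(w, p.gamma)]
    genes = w.gene_ids
    modules = [sorted(m) for m in raw if len(m) >= p.min_size]
    ms = ModuleSet([[genes[i] for i in m] for m in modules], params=vars(p).copy())
    return merge_overlapping(ms, p.beta)


def merge_overlapping(ms: ModuleSet, beta: float) -> ModuleSet:
    """Merge module pairs with overlap ratio > beta, iterating to a fixpoint."""
    mods = [frozenset(m) for m in ms.modules]
    changed = True
    while changed:
        changed = False
        # deterministic order: largest first, then lexicographic gene list
        mods.sort(key=lambda m: (-len(m), sorted(m)))
        out: list[frozenset] = []
        for m in mods:
            merged = False
            for idx, o in enumerate(out):
                overlap = len(m & o) / min(len(m), len(o))
                if overlap > beta:
                    out[idx] = o | m
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append(m)
        mods = out
    mods.sort(key=lambda m: (-len(m), sorted(m)))
    return ModuleSet([sorted(m) for m in mods], platform=ms.platform, params=dict(ms.params))


def module_density(W: np.ndarray, gene_ids: list[str], module: list[str]) -> float:
    """Mean pairwise edge weight of a module on the mining weight matrix."""
    idx = [gene_ids.index(g) for g in module]
    sub = W[np.ix_(idx, idx)]
    m = len(idx)
    return float(sub.sum() / (m * (m - 1)))


class LmqcmMiner(BaseEstimator):
    """lmQCM co-expression module miner with a scikit-learn estimator surface.

    Parameters mirror the published algorithm: ``gamma`` gates module
    initiation (seed edges must reach gamma * max edge weight), ``lambda_``
    and ``t_density`` set the adaptive density coefficient, ``beta`` the
    overlap-merge threshold.  ``fit`` expects an :class:`ExpressionMatrix`
    (genes x samples); mined gene modules land in ``modules_``.

    ``normalize`` applies the spectral-style degree normalization before
    mining.  It is off by default, matching the published miner's default:
    on small networks the normalized weight scale varies inversely with
    module size, so the relative seed gate gamma * w_max suppresses larger
    modules; on genome-scale networks, where background degree dominates,
    either setting behaves similarly.
    """

    def __init__(self, gamma=0.80, lambda_=2.0, t_density=1.0, beta=0.4,
                 min_size=10, normalize=False):
        self.gamma = gamma
        self.lambda_ = lambda_
        self.t_density = t_density
        self.beta = beta
        self.min_size = min_size
        self.normalize = normalize

    def fit(self, X: ExpressionMatrix, y=None):
        params = LmqcmParams(self.gamma, self.lambda_, self.t_density,
                             self.beta, self.min_size)
        w = spearman_weights(X)
        if self.normalize:
            w = normalize_weights(w)
        self.weight_matrix_ = w
        ms = mine_modules(w, params)
        ms.platform = X.platform
        self.modules_ = ms
        return self

    def fit_predict(self, X: ExpressionMatrix, y=None) -> ModuleSet:
        return self.fit(X).modules_
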