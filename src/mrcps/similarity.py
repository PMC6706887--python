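"""Molecular patient-similarity matrices.

Two constructions, both on top of a base K-means clustering of the patients
in eigengene space:

* cluster-density affinity -- each patient gets a Gaussian kernel density
  estimated within its molecular cluster; the affinity of two same-cluster
  patients is the product of their densities, cross-cluster affinity is 0;
* scaled exponential kernel -- W(i,j) = exp(-d^2(x_i, x_j) / (mu * eps_ij))
  with a locally scaled bandwidth eps_ij built from each patient's mean
  distance to its cluster co-members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .eigengene import EigengeneMatrix
from .io import Partition, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class DensityKernelConfig:
    h: float | str = "auto"   # bandwidth; "auto" = Silverman's rule per cluster
    base_k: int = 3
    rescale: bool = True      # divide off-diagonal entries by their maximum

    def __post_init__(self):
        if self.h != "auto" and (not np.isreal(self.h) or self.h <= 0):
            raise ValueError("bandwidth h must be positive or 'auto'")


@dataclass
class ExpKernelConfig:
    mu: float = 0.5
    base_k: int = 3

    def __post_init__(self):
        if not 0 < self.mu <= 1:
            raise ValueError("mu must be in (0, 1]")


def base_cluster(eg: EigengeneMatrix, k: int, seed: int = 0, n_init: int = 20) -> Partition:
    """K-means over patients in eigengene space (best inertia of n_init restarts)."""
    x = eg.features()
    n = x.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x)
    return Partition(eg.sample_ids, labels)


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule on the pooled per-feature SD, d-dimensional form."""
    n, p = x.shape
    sd = float(np.sqrt(np.mean(np.var(x, axis=0, ddof=1)))) if n > 1 else 1.0
    if sd == 0:
        sd = 1.0
    return sd * (4.0 / ((p + 2) * n)) ** (1.0 / (p + 4))


def density_affinity(eg: EigengeneMatrix, part: Partition,
                     cfg: DensityKernelConfig | None = None) -> SimilarityMatrix:
    """Cluster-density affinity matrix.

    f(i) = (1 / (N_i (2 pi h^2)^{p/2})) * sum_{j in cluster(i)} exp(-||x_i-x_j||^2 / (2 h^2));
    W(i,j) = f(i) f(j) for distinct same-cluster patients, 0 across clusters,
    1 on the diagonal.  With ``rescale`` the off-diagonal block values are
    divided by their maximum so downstream fusion operates on a [0, 1] scale.
    """
    if cfg is None:
        cfg = DensityKernelConfig()
    x = eg.features()
    n, p = x.shape
    if list(part.sample_ids) != list(eg.sample_ids):
        raise ValueError("partition does not cover the eigengene samples")
    f = np.zeros(n)
    for lab in np.unique(part.labels):
        idx = np.where(part.labels == lab)[0]
        xc = x[idx]
        h = _silverman_bandwidth(xc) if cfg.h == "auto" else float(cfg.h)
        if h <= 0:
            raise ValueError("bandwidth h must be positive")
        d2 = squareform(pdist(xc, "sqeuclidean")) if len(idx) > 1 else np.zeros((1, 1))
        kern = np.exp(-d2 / (2.0 * h * h))
        f[idx] = kern.sum(axis=1) / (len(idx) * (2.0 * np.pi * h * h) ** (p / 2.0))
    same = part.labels[:, None] == part.labels[None, :]
    W = np.where(same, np.outer(f, f), 0.0)
    np.fill_diagonal(W, 0.0)
    if cfg.rescale and W.max() > 0:
        W = W / W.max()
    np.fill_diagonal(W, 1.0)
    return SimilarityMatrix(list(eg.sample_ids), W, kind="density")


def exp_kernel(eg: EigengeneMatrix, part: Partition,
               cfg: ExpKernelConfig | None = None) -> SimilarityMatrix:
    """Scaled exponential similarity kernel with cluster-local bandwidths.

    eps_ij = [mean d(x_i, cluster(i) \\ {i}) + mean d(x_j, cluster(j) \\ {j})
              + d(x_i, x_j)] / 3;  W(i,j) = exp(-d^2(x_i,x_j) / (mu * eps_ij)).
    """
    if cfg is None:
        cfg = ExpKernelConfig()
    x = eg.features()
    n = x.shape[0]
    if list(part.sample_ids) != list(eg.sample_ids):
        raise ValueError("partition does not cover the eigengene samples")
    d = squareform(pdist(x, "euclidean"))
    mean_d = np.zeros(n)
    for lab in np.unique(part.labels):
        idx = np.where(part.labels == lab)[0]
        if len(idx) < 2:
            raise ValueError("every cluster must have >= 2 members")
        sub = d[np.ix_(idx, idx)]
        mean_d[idx] = sub.sum(axis=1) / (len(idx) - 1)
    eps = (mean_d[:, None] + mean_d[None, :] + d) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.exp(-(d**2) / (cfg.mu * eps))
    W[eps == 0] = 1.0  # coincident points within a degenerate cluster
    if (eps == 0).all():
        logger.warning("all points coincide; exponential kernel is all ones")
    np.fill_diagonal(W, 1.0)
    W = (W + W.T) / 2.0
    return SimilarityMatrix(list(eg.sample_ids), W, kind="kernel")


class PatientSimilarity(BaseEstimator):
    """Estimator building a molecular patient-similarity matrix.

    ``method`` selects the cluster-density affinity ("density") or the scaled
    exponential kernel ("kernel"); ``base_k`` is the K-means cluster count for
    the underlying molecular clustering.
    """

    def __init__(self, method="density", base_k=3, h="auto", mu=0.5,
                 rescale=True, seed=0):
        self.method = method
        self.base_k = base_k
        self.h = h
        self.mu = mu
        self.rescale = rescale
        self.seed = seed

    def fit(self, X: EigengeneMatrix, y=None):
        self.base_partition_ = base_cluster(X, self.base_k, seed=self.seed)
        if self.method == "density":
            cfg = DensityKernelConfig(h=self.h, base_k=self.base_k, rescale=self.rescale)
            self.similarity_ = density_affinity(X, self.base_partition_, cfg)
        elif self.method == "kernel":
            cfg = ExpKernelConfig(mu=self.mu, base_k=self.base_k)
            self.similarity_ = exp_kernel(X, self.base_partition_, cfg)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self

    def fit_transform(self, X: EigengeneMatrix, y=None) -> SimilarityMatrix:
        return self.fit(X).similarity_
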