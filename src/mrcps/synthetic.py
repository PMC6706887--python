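"""Two-platform synthetic cohorts with planted co-expression modules.

The generator emulates the statistical structure the stratification workflow
assumes: two expression platforms sharing a subset of gene symbols, planted
latent-factor co-expression modules, patient subgroups separable in eigengene
space, stage/risk labels correlated with the subgroups, and subgroup-dependent
exponential survival with independent uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ClinicalTable, ExpressionMatrix, ModuleSet, Partition


@dataclass
class CohortConfig:
    n_patients: int = 150
    n_genes_per_platform: int = 200
    n_shared_genes: int = 200
    n_modules: int = 5
    module_size_range: tuple[int, int] = (10, 30)
    factor_loading: float = 0.85   # lower bound of per-gene loadings on the module factor
    noise_sd: float = 0.25         # SD of additive gene-level noise
    n_subgroups: int = 3
    subgroup_hazards: tuple[float, ...] = (0.08, 0.03, 0.01)  # events / month
    censor_rate: float = 0.2
    stage_confusion: float = 0.1   # probability a stage label is drawn at random
    subgroup_separation: float = 5.0  # pairwise distance between subgroup factor-mean
    # vectors, in within-subgroup factor-SD units; 5 keeps subgroups well separated
    # in eigengene space, which the stratification workflow assumes
    weibull_shape: float = 1.0     # 1 = exponential survival
    seed: int = 0

    def __post_init__(self):
        if self.n_shared_genes > self.n_genes_per_platform:
            raise ValueError("n_shared_genes cannot exceed n_genes_per_platform")
        if len(self.subgroup_hazards) != self.n_subgroups:
            raise ValueError("one hazard per subgroup required")
        if self.module_size_range[0] < 3:
            raise ValueError("module sizes must be >= 3")
        if not 0 < self.factor_loading <= 1:
            raise ValueError("factor_loading must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if any(h <= 0 for h in self.subgroup_hazards):
            raise ValueError("hazards must be positive")


@dataclass
class SyntheticCohort:
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    clinical: ClinicalTable
    true_modules_a: ModuleSet
    true_modules_b: ModuleSet
    true_subgroups: Partition
    factors: np.ndarray = field(repr=False, default=None)  # modules x patients latent factors


def generate(config: CohortConfig) -> SyntheticCohort:
    """Generate a reproducible two-platform cohort from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    sample_ids = [f"P{i:04d}" for i in range(n)]

    # planted module gene sets live in the shared gene block
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    if sizes.sum() > config.n_shared_genes:
        raise ValueError("planted module sizes exceed the shared gene count")

    shared = [f"G{i:04d}" for i in range(config.n_shared_genes)]
    gene_iter = iter(shared)
    modules = [[next(gene_iter) for _ in range(s)] for s in sizes]

    # subgroups and module factors: factor f_m = center[m, subgroup] + N(0,1)
    subgroup = rng.integers(0, config.n_subgroups, size=n)
    centers = _subgroup_centers(rng, config.n_modules, config.n_subgroups,
                                config.subgroup_separation)
    factors = centers[:, subgroup] + rng.normal(0.0, 1.0, size=(config.n_modules, n))

    def platform_matrix() -> pd.DataFrame:
        extra = config.n_genes_per_platform - config.n_shared_genes
        x = rng.normal(0.0, 1.0, size=(config.n_genes_per_platform, n))
        for m, genes in enumerate(modules):
            idx = [shared.index(g) for g in genes]
            loadings = rng.uniform(config.factor_loading, 1.0, size=len(genes))
            x[idx, :] = loadings[:, None] * factors[m][None, :]
            x[idx, :] += rng.normal(0.0, config.noise_sd, size=(len(genes), n))
        return x, extra

    xa, extra = platform_matrix()
    genes_a = shared + [f"A{i:04d}" for i in range(extra)]
    xb, extra = platform_matrix()
    genes_b = shared + [f"B{i:04d}" for i in range(extra)]

    expr_a = ExpressionMatrix(
        pd.DataFrame(xa, index=genes_a, columns=sample_ids), platform="synthetic", scale="raw"
    )
    expr_b = ExpressionMatrix(
        pd.DataFrame(xb, index=genes_b, columns=sample_ids), platform="synthetic", scale="raw"
    )

    clinical = _clinical_table(config, rng, sample_ids, subgroup)

    truth_a = ModuleSet(modules, platform="synthetic", params={"planted": True})
    truth_b = ModuleSet(modules, platform="synthetic", params={"planted": True})
    return SyntheticCohort(
        expr_a=expr_a,
        expr_b=expr_b,
        clinical=clinical,
        true_modules_a=truth_a,
        true_modules_b=truth_b,
        true_subgroups=Partition(sample_ids, subgroup),
        factors=factors,
    )


def _subgroup_centers(rng, n_modules: int, n_subgroups: int, separation: float) -> np.ndarray:
    """Subgroup factor-mean vectors (modules x subgroups).

    The centers form a regular simplex with pairwise distance ``separation``,
    randomly oriented in module-factor space, so the nominal spacing is
    guaranteed for every seed rather than realized on average.  When
    n_modules < n_subgroups - 1 the simplex cannot be embedded isometrically
    and distances contract (best effort).
    """
    k = n_subgroups
    simplex = (np.eye(k) - 1.0 / k) * separation / np.sqrt(2.0)  # k points in R^k
    G = rng.normal(size=(max(n_modules, k), k))
    Q, _ = np.linalg.qr(G)  # orthonormal columns
    centers = Q[:n_modules, :k] @ simplex.T
    return centers


def _clinical_table(config, rng, sample_ids, subgroup) -> ClinicalTable:
    hazards = np.asarray(config.subgroup_hazards, dtype=float)
    n = len(sample_ids)

    # stage: subgroups ordered worst-to-best map onto INSS stages 4,3,2,1,4S
    order = np.argsort(-hazards)
    stage_of_subgroup = {}
    stage_cycle = ["4", "3", "2", "1", "4S"]
    for rank, s in enumerate(order):
        stage_of_subgroup[s] = stage_cycle[rank % len(stage_cycle)]
    stage = np.array([stage_of_subgroup[s] for s in subgroup], dtype=object)
    confused = rng.random(n) < config.stage_confusion
    # mislabels stay within the stage levels in use, so the stage signal remains a
    # noisy view of the subgroups rather than acquiring spurious categories
    used_stages = sorted(set(stage_of_subgroup.values()))
    stage[confused] = rng.choice(used_stages, size=int(confused.sum()))

    risk = np.where(hazards[subgroup] > np.median(hazards), "high", "low")

    # survival: Weibull(shape, scale=1/hazard); shape 1 -> exponential
    scale = 1.0 / hazards[subgroup]
    t_true = scale * rng.weibull(config.weibull_shape, size=n)

    if config.censor_rate == 0:
        os_time, os_event = t_true, np.ones(n, dtype=int)
    else:
        c_max = _uniform_censor_bound(hazards, config.censor_rate)
        c = rng.uniform(0.0, c_max, size=n)
        os_event = (t_true <= c).astype(int)
        os_time = np.minimum(t_true, c)

    table = pd.DataFrame(
        {
            "stage": stage,
            "risk": risk,
            "os_time": os_time,
            "os_event": os_event,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ClinicalTable(table)


def _uniform_censor_bound(hazards: np.ndarray, censor_rate: float) -> float:
    """Upper bound M for Uniform(0, M) censoring achieving the target rate.

    For T ~ Exp(h), C ~ U(0, M): P(censored) = P(C < T) = (1 - exp(-hM)) / (hM),
    averaged over subgroups (equal subgroup proportions in expectation).
    """

    def mean_censor_prob(m):
        return float(np.mean((1.0 - np.exp(-hazards * m)) / (hazards * m)))

    lo, hi = 1e-9, 1.0
    while mean_censor_prob(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e9:
            break
    return brentq(lambda m: mean_censor_prob(m) - censor_rate, lo, hi)
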