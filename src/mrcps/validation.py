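"""Self-contained validation experiments for the stratification workflow.

Each function generates its own synthetic inputs, runs the relevant part of
the package, and returns summary statistics.  They back both the test suite
and the reproduction script; problem sizes are chosen so the full battery
runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .consensus import ConsensusProblem, nmi, optimize_partition, select_k
from .eigengene import eigengenes
from .fusion import MatrixFusion, SnfConfig, snf_fuse
from .io import ExpressionMatrix, Partition, SimilarityMatrix, zscore
from .mining import LmqcmMiner
from .pipeline import molecular_base_partition
from .similarity import DensityKernelConfig, ExpKernelConfig, density_affinity, exp_kernel
from .survival import differential_expression, logrank
from .synthetic import CohortConfig, generate


def module_recovery(seed: int = 0) -> dict:
    """Mine a 200-gene cohort with 5 planted modules at default lmQCM
    parameters; report best-match Jaccard per planted module."""
    cfg = CohortConfig(
        n_patients=150, n_genes_per_platform=200, n_shared_genes=200,
        n_modules=5, module_size_range=(10, 30), factor_loading=0.85,
        noise_sd=0.25, n_subgroups=3, subgroup_hazards=(0.08, 0.03, 0.01),
        seed=seed,
    )
    cohort = generate(cfg)
    mined = LmqcmMiner().fit_predict(zscore(cohort.expr_a))
    jaccards = []
    for planted in cohort.true_modules_a.modules:
        ts = set(planted)
        best = max((len(ts & set(m)) / len(ts | set(m)) for m in mined.modules),
                   default=0.0)
        jaccards.append(best)
    return {
        "jaccards": jaccards,
        "min_jaccard": min(jaccards),
        "n_mined": len(mined),
        "n_planted": len(cohort.true_modules_a),
    }


def consensus_optimality(seed: int = 0, n_trials: int = 20, n: int = 7) -> dict:
    """Spectral-relaxation objective vs the exhaustive global optimum on
    random small consensus problems; report the worst objective ratio."""
    rng = np.random.default_rng(seed)
    worst = 1.0
    for trial in range(n_trials):
        A = rng.uniform(size=(n, n))
        W = (A + A.T) / 2
        np.fill_diagonal(W, 1.0)
        ids = [f"p{i}" for i in range(n)]
        parts = [Partition(ids, rng.integers(0, 3, n)) for _ in range(2)]
        k = int(rng.integers(2, 5))
        prob = ConsensusProblem(parts, SimilarityMatrix(ids, W),
                                seed=int(rng.integers(1 << 30)))
        ex = optimize_partition(prob, k, exhaustive=True)
        sp = optimize_partition(prob, k)
        if ex.objective > 0:
            worst = max(worst, sp.objective / ex.objective)
    return {"worst_ratio": worst, "n_trials": n_trials, "n_samples": n}


def subgroup_recovery(seed: int = 0, n_seeds: int = 10) -> dict:
    """Full workflow on aligned-signal cohorts with 3 planted subgroups:
    mine, summarize, density-affinity, geometric fusion, NMI k-selection.
    Reports how often k = 3 is chosen with ARI >= 0.9 against truth."""
    successes, ks, aris = 0, [], []
    for s in range(n_seeds):
        cohort_seed = (seed + s) % (1 << 31)
        cfg = CohortConfig(
            n_patients=120, n_genes_per_platform=150, n_shared_genes=150,
            n_modules=4, module_size_range=(10, 25), factor_loading=0.85,
            noise_sd=0.25, n_subgroups=3, subgroup_hazards=(0.08, 0.03, 0.01),
            censor_rate=0.2, stage_confusion=0.0, seed=cohort_seed,
        )
        cohort = generate(cfg)
        za, zb = zscore(cohort.expr_a), zscore(cohort.expr_b)
        egs = [eigengenes(z, LmqcmMiner().fit_predict(z)) for z in (za, zb)]
        k_range = (2, 3, 4, 5, 6)
        bases = [molecular_base_partition(e.features(), za.sample_ids,
                                          k_range, cohort_seed) for e in egs]
        sims = [density_affinity(e, b, DensityKernelConfig())
                for e, b in zip(egs, bases)]
        fused = MatrixFusion(method="geometric").fit_transform(tuple(sims))
        clin = [cohort.clinical.stage_partition(), cohort.clinical.risk_partition()]
        mol = molecular_base_partition(
            np.hstack([e.features() for e in egs]), za.sample_ids, k_range, cohort_seed)
        prob = ConsensusProblem(clin, fused, k_range=k_range, seed=cohort_seed)
        res = select_k(prob, base=clin + [mol])
        ari = adjusted_rand_score(cohort.true_subgroups.labels, res.partition.labels)
        ks.append(res.k)
        aris.append(ari)
        successes += int(res.k == 3 and ari >= 0.9)
    return {"successes": successes, "n_seeds": n_seeds, "ks": ks,
            "aris": aris, "mean_ari": float(np.mean(aris))}


def kernel_handchecks() -> dict:
    """Closed-form boundary cases of the similarity kernels and fusions;
    reports the largest absolute deviation."""
    errs = []

    # density affinity: diagonal 1, cross-cluster 0, coincident-pair value
    eg = _eg(np.array([[0.0], [0.0], [5.0], [5.0]]))
    part = Partition(eg.sample_ids, np.array([0, 0, 1, 1]))
    s = density_affinity(eg, part, DensityKernelConfig(h=1.0, rescale=False))
    errs.append(abs(s.W[0, 0] - 1.0))
    errs.append(abs(s.W[0, 2]))
    errs.append(abs(s.W[0, 1] - 1.0 / (2 * np.pi)))

    # scaled exponential kernel: 3-point worked example
    eg3 = _eg(np.array([[0.0], [1.0], [4.0]]))
    s3 = exp_kernel(eg3, Partition(eg3.sample_ids, np.zeros(3, int)),
                    ExpKernelConfig(mu=0.5))
    errs.append(abs(s3.W[0, 1] - np.exp(-12.0 / 11.0)))
    errs.append(abs(s3.W[0, 0] - 1.0))

    # geometric fusion idempotence on equal inputs
    rng = np.random.default_rng(1)
    A = rng.uniform(0.0, 1.0, (5, 5))
    W = (A + A.T) / 2
    np.fill_diagonal(W, 1.0)
    sw = SimilarityMatrix([f"p{i}" for i in range(5)], W)
    fused = MatrixFusion(method="geometric").fit_transform((sw, sw))
    errs.append(np.abs(fused.W - W).max())

    # SNF two-sample fixed point
    w2 = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.4], [0.4, 1.0]]))
    out = snf_fuse(w2, w2, SnfConfig(K=1, iters=10))
    errs.append(np.abs(out.W - 0.5).max())

    return {"max_abs_error": float(max(errs)), "n_checks": len(errs)}


def logrank_null_calibration(seed: int = 0, n_reps: int = 2000,
                             n_per_group: int = 100) -> dict:
    """Type-I error of the log-rank test at alpha = 0.05 under equal
    exponential hazards."""
    rng = np.random.default_rng(seed)
    g = np.repeat([0, 1], n_per_group)
    e = np.ones(2 * n_per_group, int)
    rejections = 0
    for _ in range(n_reps):
        t = rng.exponential(20.0, size=2 * n_per_group)
        _, p = logrank(t, e, g)
        rejections += p < 0.05
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def nmi_checks(seed: int = 0, n_pairs: int = 1000) -> dict:
    """NMI boundary values and range over random label pairs."""
    rng = np.random.default_rng(seed)
    ids4 = [f"p{i}" for i in range(4)]
    orthogonal = nmi(Partition(ids4, [1, 1, 2, 2]), Partition(ids4, [1, 2, 1, 2]))
    identical = nmi(Partition(ids4, [0, 0, 1, 1]), Partition(ids4, [0, 0, 1, 1]))
    out_of_range = 0
    for _ in range(n_pairs):
        n = int(rng.integers(4, 40))
        ids = [f"p{i}" for i in range(n)]
        v = nmi(Partition(ids, rng.integers(0, 4, n)),
                Partition(ids, rng.integers(0, 4, n)))
        out_of_range += not (0.0 <= v <= 1.0)
    return {"orthogonal": orthogonal, "identical": identical,
            "out_of_range": out_of_range, "n_pairs": n_pairs}


def de_filter(seed: int = 0, n_seeds: int = 5) -> dict:
    """Planted 4-fold shifts in 50 of 500 genes, 30 samples per group:
    sensitivity of the fold-change + FDR filter and background false calls."""
    sens, fps = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng((seed + s) % (1 << 31))
        n_genes, n_per = 500, 30
        base = rng.uniform(3, 8, n_genes)
        planted = rng.choice(n_genes, 50, replace=False)
        mu_a = base.copy()
        mu_a[planted] += 2.0  # 4-fold on the raw scale
        la = rng.normal(mu_a[:, None], 0.25, (n_genes, n_per))
        lb = rng.normal(base[:, None], 0.25, (n_genes, n_per))
        ids = [f"A{i}" for i in range(n_per)] + [f"B{i}" for i in range(n_per)]
        e = ExpressionMatrix(pd.DataFrame(
            np.hstack([2.0**la, 2.0**lb]),
            index=[f"g{i}" for i in range(n_genes)], columns=ids))
        res = differential_expression(e, ids[:n_per], ids[n_per:])
        hits = set(np.where(res.table["passed"].to_numpy())[0])
        sens.append(len(hits & set(planted)) / 50)
        fps.append(len(hits - set(planted)))
    return {"sensitivities": sens, "min_sensitivity": min(sens),
            "false_positives": fps, "max_false_positives": max(fps),
            "n_seeds": n_seeds}


def _eg(x: np.ndarray):
    from .eigengene import EigengeneMatrix

    values = pd.DataFrame(x.T, index=[f"M{j}" for j in range(x.shape[1])],
                          columns=[f"p{i}" for i in range(x.shape[0])])
    return EigengeneMatrix(values, np.ones(x.shape[1]))
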