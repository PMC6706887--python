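"""End-to-end orchestration: mine -> eigengenes -> similarity -> fuse -> stratify -> evaluate."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from . import io as mio
from .consensus import ConsensusProblem, select_k
from .eigengene import eigengenes, write_eigengenes
from .mining import LmqcmMiner
from .similarity import PatientSimilarity
from .fusion import MatrixFusion
from .survival import kaplan_meier, km_table, logrank

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expr_a: str = ""
    expr_b: str = ""
    clinical: str = ""
    platform_a: str = "microarray"
    platform_b: str = "rnaseq"
    lmqcm: dict = field(default_factory=dict)          # gamma, lambda_, t_density, beta, min_size
    similarity_method: str = "density"                 # density | kernel
    base_k: int = 3
    mu: float = 0.5
    bandwidth: str | float = "auto"
    fusion_method: str = "geometric"                   # geometric | snf
    snf_K: int | None = None
    snf_iters: int = 20
    clinical_partitions: tuple[str, ...] = ("stage", "risk")
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    seed: int = 0
    out_dir: str = "mrcps_out"

    def validate(self) -> None:
        for name in ("expr_a", "expr_b", "clinical"):
            path = getattr(self, name)
            if not path:
                raise ValueError(f"config missing required path {name!r}")
            if not Path(path).exists():
                raise ValueError(f"{name} path does not exist: {path}")
        if self.similarity_method not in ("density", "kernel"):
            raise ValueError("similarity_method must be 'density' or 'kernel'")
        if self.fusion_method not in ("geometric", "snf"):
            raise ValueError("fusion_method must be 'geometric' or 'snf'")
        if not self.clinical_partitions:
            raise ValueError("at least one clinical partition required")
        if any(p not in ("stage", "risk") for p in self.clinical_partitions):
            raise ValueError("clinical_partitions entries must be 'stage' or 'risk'")
        if not self.k_range:
            raise ValueError("empty k_range")


def molecular_base_partition(features: np.ndarray, sample_ids, k_range, seed) -> mio.Partition:
    """K-means base clustering with k chosen by silhouette over k_range."""
    best_k, best_s, best_labels = None, -np.inf, None
    for k in sorted(k_range):
        if not 2 <= k < len(sample_ids):
            continue
        labels = KMeans(n_clusters=k, n_init=20, random_state=seed).fit_predict(features)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(features, labels)
        if s > best_s:
            best_k, best_s, best_labels = k, s, labels
    if best_labels is None:
        raise ValueError("no valid k for the molecular base clustering")
    logger.info("molecular base clustering: k=%d (silhouette %.3f)", best_k, best_s)
    return mio.Partition(list(sample_ids), best_labels)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full stratification workflow; write artifacts and a JSON report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(asdict(cfg)), "stages": {}}
    t0 = time.time()

    # timings go to the log, not the report, so reports are reproducible byte-for-byte
    def stage_done(name):
        logger.info("stage %s done at %.2fs", name, time.time() - t0)
        report["stages"].setdefault(name, {})

    expr_a = mio.load_expression(cfg.expr_a, platform=cfg.platform_a)
    expr_b = mio.load_expression(cfg.expr_b, platform=cfg.platform_b)
    clinical = mio.load_clinical(cfg.clinical)
    expr_a, expr_b = mio.intersect_genes(expr_a, expr_b)
    za, zb = mio.zscore(expr_a), mio.zscore(expr_b)
    samples = za.sample_ids
    if samples != zb.sample_ids or set(samples) - set(clinical.sample_ids):
        raise ValueError("sample IDs inconsistent across inputs")
    clinical = mio.ClinicalTable(clinical.table.loc[samples])
    stage_done("load")

    modules, egs = {}, {}
    for tag, z in (("a", za), ("b", zb)):
        miner = LmqcmMiner(**cfg.lmqcm)
        ms = miner.fit_predict(z)
        if len(ms) == 0:
            raise ValueError(f"mining produced no modules on platform {tag}")
        modules[tag] = ms
        mio.write_gmt(ms, out / f"modules_{tag}.gmt")
        egs[tag] = eigengenes(z, ms)
        write_eigengenes(egs[tag], out / f"eigengenes_{tag}.tsv")
    report["stages"]["mine"] = {
        "n_modules_a": len(modules["a"]), "n_modules_b": len(modules["b"]),
    }
    logger.info("stage mine done at %.2fs", time.time() - t0)

    sims = {}
    for tag in ("a", "b"):
        est = PatientSimilarity(method=cfg.similarity_method, base_k=cfg.base_k,
                                h=cfg.bandwidth, mu=cfg.mu, seed=cfg.seed)
        sims[tag] = est.fit_transform(egs[tag])
        mio.write_similarity(sims[tag], out / f"similarity_{tag}.tsv")
    stage_done("similarity")

    fused = MatrixFusion(method=cfg.fusion_method, K=cfg.snf_K,
                         iters=cfg.snf_iters).fit_transform((sims["a"], sims["b"]))
    mio.write_similarity(fused, out / "fused.tsv")
    stage_done("fuse")

    clin_parts = []
    for name in cfg.clinical_partitions:
        part = clinical.stage_partition() if name == "stage" else clinical.risk_partition()
        clin_parts.append(part)
    features = np.hstack([egs["a"].features(), egs["b"].features()])
    mol_base = molecular_base_partition(features, samples, cfg.k_range, cfg.seed)
    problem = ConsensusProblem(clin_parts, fused, k_range=tuple(cfg.k_range), seed=cfg.seed)
    result = select_k(problem, base=clin_parts + [mol_base])
    mio.write_partition(result.partition, out / "partition.csv")
    report["stages"]["stratify"] = {
        "k": result.k, "objective": result.objective, "nmi_score": result.nmi_score,
        "per_k": result.per_k,
    }
    logger.info("stage stratify done at %.2fs", time.time() - t0)

    tbl = clinical.table
    curves = kaplan_meier(tbl["os_time"], tbl["os_event"], result.partition.labels)
    km_table(curves).to_csv(out / "km.tsv", sep="\t", index=False, lineterminator="\n")
    chi2, p = logrank(tbl["os_time"], tbl["os_event"], result.partition.labels)
    report["stages"]["evaluate"] = {"logrank_chi2": chi2, "logrank_p": p}
    logger.info("stage evaluate done at %.2fs", time.time() - t0)
    report["k"] = result.k
    report["logrank_p"] = p

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
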