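"""Containers and text-format I/O for expression, clinical, module and matrix data.

Expression matrices are tab-separated text with gene symbols in the first
column and patient IDs in the header row.  Module sets use the GMT gene-set
format, similarity matrices a TSV with a sample-ID header row and column,
partitions and clinical tables plain CSV.  All files are UTF-8 with LF line
endings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGE_LEVELS = ("1", "2", "3", "4", "4S")
RISK_LEVELS = ("high", "low")
PLATFORMS = ("microarray", "rnaseq", "synthetic")
SCALES = ("raw", "log", "zscore")


class FormatError(ValueError):
    """A file violated the expected text format."""


@dataclass
class ExpressionMatrix:
    """Genes x patients numeric matrix with a platform and scale tag."""

    values: pd.DataFrame  # index: gene symbols, columns: patient IDs
    platform: str = "synthetic"
    scale: str = "raw"

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if self.values.isna().to_numpy().any():
            raise ValueError("missing values in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClinicalTable:
    """Per-patient INSS stage, risk level and overall-survival endpoint."""

    table: pd.DataFrame  # index: sample_id; columns: stage, risk, os_time, os_event

    def __post_init__(self):
        t = self.table
        required = {"stage", "risk", "os_time", "os_event"}
        if missing := required - set(t.columns):
            raise ValueError(f"clinical table missing columns {sorted(missing)}")
        if t.index.has_duplicates:
            raise ValueError("duplicate sample IDs in clinical table")
        bad_stage = set(t["stage"].astype(str)) - set(STAGE_LEVELS)
        if bad_stage:
            raise ValueError(f"unknown stage levels {sorted(bad_stage)}")
        bad_risk = set(t["risk"].astype(str)) - set(RISK_LEVELS)
        if bad_risk:
            raise ValueError(f"unknown risk levels {sorted(bad_risk)}")
        if (t["os_time"] < 0).any():
            raise ValueError("negative survival times")
        if not t["os_event"].isin([0, 1]).all():
            raise ValueError("os_event must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def stage_partition(self) -> "Partition":
        return Partition.from_categorical(self.sample_ids, self.table["stage"].astype(str))

    def risk_partition(self) -> "Partition":
        return Partition.from_categorical(self.sample_ids, self.table["risk"].astype(str))


@dataclass
class Partition:
    """Cluster labels over a fixed sample set, with its pairwise connectivity."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("labels and sample_ids length mismatch")
        if len(self.labels) == 0:
            raise ValueError("empty partition")

    @classmethod
    def from_categorical(cls, sample_ids, values) -> "Partition":
        codes, _ = pd.factorize(pd.Series(list(values)), sort=True)
        return cls(list(sample_ids), codes)

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))

    def connectivity(self) -> np.ndarray:
        """0/1 matrix, entry 1 iff two samples share a label; diagonal 1."""
        lab = self.labels
        return (lab[:, None] == lab[None, :]).astype(float)


@dataclass
class ModuleSet:
    """Gene modules mined from one platform; genes may be shared across modules."""

    modules: list[list[str]]
    platform: str = "synthetic"
    params: dict = field(default_factory=dict)
    names: list[str] | None = None

    def __post_init__(self):
        self.modules = [list(m) for m in self.modules]
        if self.names is None:
            self.names = [f"M{i + 1}" for i in range(len(self.modules))]

    def __len__(self) -> int:
        return len(self.modules)

    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules]


@dataclass
class SimilarityMatrix:
    """Symmetric non-negative patient-affinity matrix."""

    sample_ids: list[str]
    W: np.ndarray
    kind: str = "kernel"  # density | kernel | fused_geometric | fused_snf

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.sample_ids)
        if self.W.shape != (n, n):
            raise ValueError("matrix shape does not match sample_ids")
        if not np.allclose(self.W, self.W.T, atol=1e-12):
            raise ValueError("similarity matrix not symmetric")
        if (self.W < 0).any():
            raise ValueError("negative similarity entries")


# ---------------------------------------------------------------------------
# Expression I/O and preprocessing


def load_expression(path, platform: str = "synthetic", scale: str = "raw") -> ExpressionMatrix:
    """Read a genes-x-samples TSV.

    Rows with any missing value are dropped (count logged); duplicate gene
    symbols are collapsed by keeping the highest-variance row (logged).
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise FormatError(f"duplicate sample IDs: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # NA-like tokens become missing (row dropped below); anything else is a parse error
            for gene, val in df.loc[bad, col].items():
                if not _is_na_token(val):
                    raise FormatError(
                        f"non-numeric value {val!r} at gene {gene!r}, sample {col!r}"
                    )
        df[col] = coerced
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    if len(df) < n_before:
        logger.warning("dropped %d gene rows containing missing values", n_before - len(df))
    if df.index.has_duplicates:
        var = df.var(axis=1, ddof=1)
        order = np.argsort(-var.to_numpy(), kind="stable")
        df = df.iloc[order]
        n_dup = int(df.index.duplicated(keep="first").sum())
        df = df[~df.index.duplicated(keep="first")]
        df = df.sort_index()
        logger.warning("collapsed %d duplicate gene symbols (kept max-variance row)", n_dup)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, platform=platform, scale=scale)


def _is_na_token(v) -> bool:
    return str(v).strip().upper() in {"NA", "NAN", "NULL", ""}


def write_expression(e: ExpressionMatrix, path) -> None:
    e.values.to_csv(path, sep="\t", lineterminator="\n")


def intersect_genes(a: ExpressionMatrix, b: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, lexicographic order."""
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise ValueError("empty gene intersection between platforms")
    return (
        replace(a, values=a.values.loc[common]),
        replace(b, values=b.values.loc[common]),
    )


def zscore(e: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene standardization across samples (sample SD, n-1 denominator).

    Constant genes are removed (logged) rather than divided by zero.
    """
    if e.scale == "zscore":
        raise ValueError("matrix is already z-scored")
    if e.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    v = e.values
    sd = v.std(axis=1, ddof=1)
    const = sd <= 0
    if const.any():
        logger.warning("dropping %d constant gene rows before z-scoring", int(const.sum()))
        v = v.loc[~const]
        sd = sd.loc[~const]
    z = v.sub(v.mean(axis=1), axis=0).div(sd, axis=0)
    return replace(e, values=z, scale="zscore")


# ---------------------------------------------------------------------------
# Clinical I/O


def load_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df["stage"] = df["stage"].astype(str)
    df["risk"] = df["risk"].astype(str)
    return ClinicalTable(df)


def write_clinical(c: ClinicalTable, path) -> None:
    c.table.to_csv(path, index_label="sample_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT module sets


def write_gmt(ms: ModuleSet, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in zip(ms.names, ms.modules):
            fh.write("\t".join([name, ms.platform, *genes]) + "\n")


def read_gmt(path, platform: str = "synthetic") -> ModuleSet:
    names, modules = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"malformed GMT line {lineno}: fewer than 3 fields")
            names.append(fields[0])
            modules.append(fields[2:])
    return ModuleSet(modules, platform=platform, names=names)


# ---------------------------------------------------------------------------
# Similarity matrices and partitions


def write_similarity(s: SimilarityMatrix, path) -> None:
    pd.DataFrame(s.W, index=s.sample_ids, columns=s.sample_ids).to_csv(
        path, sep="\t", index_label="sample_id", lineterminator="\n"
    )


def read_similarity(path, kind: str = "kernel") -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("similarity matrix row/column sample IDs differ")
    W = df.to_numpy(dtype=float)
    return SimilarityMatrix(list(df.index), (W + W.T) / 2.0, kind=kind)


def write_partition(p: Partition, path) -> None:
    pd.DataFrame({"sample_id": p.sample_ids, "label": p.labels}).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_partition(path) -> Partition:
    df = pd.read_csv(path)
    return Partition(df["sample_id"].astype(str).tolist(), df["label"].to_numpy())


def validate_partition_samples(p: Partition, clinical: ClinicalTable) -> None:
    unknown = set(p.sample_ids) - set(clinical.sample_ids)
    if unknown:
        raise ValueError(f"partition contains unknown sample IDs: {sorted(unknown)[:5]}")
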