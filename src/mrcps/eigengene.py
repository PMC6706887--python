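"""Eigengene summarization: one first-principal-component profile per module."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix, ModuleSet


@dataclass
class EigengeneMatrix:
    """Modules x samples summary features.

    Each row is the first principal-component score vector of the module's
    expression submatrix, sign-oriented to correlate positively with the
    module's mean expression profile, then standardized to unit variance.
    """

    values: pd.DataFrame  # index: module names, columns: sample IDs
    explained_variance_ratio: np.ndarray

    @property
    def module_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def features(self) -> np.ndarray:
        """Samples x modules array for clustering (samples as points)."""
        return self.values.to_numpy().T


def eigengenes(e: ExpressionMatrix, ms: ModuleSet) -> EigengeneMatrix:
    """First-PC eigengene per module, computed on z-scored expression.

    PCA treats genes as variables and samples as observations; the component
    sign is fixed by positive correlation with the module mean profile
    (PCA sign is otherwise arbitrary).
    """
    if e.scale != "zscore":
        raise ValueError("eigengenes expect a z-scored expression matrix")
    rows, evr = [], []
    present = set(e.gene_ids)
    for name, genes in zip(ms.names, ms.modules):
        genes_here = sorted(set(genes) & present)
        if len(genes_here) < 2:
            raise ValueError(f"module {name!r} has < 2 genes present in the matrix")
        sub = e.values.loc[genes_here].to_numpy()  # genes x samples
        centered = sub - sub.mean(axis=1, keepdims=True)
        # first right singular vector of (genes x samples) = first PC scores over samples
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        pc = vt[0]
        var_total = (s**2).sum()
        evr.append(float(s[0] ** 2 / var_total) if var_total > 0 else 1.0)
        mean_profile = sub.mean(axis=0)
        if np.dot(pc, mean_profile - mean_profile.mean()) < 0:
            pc = -pc
        sd = pc.std(ddof=1)
        if sd > 0:
            pc = (pc - pc.mean()) / sd
        rows.append(pc)
    values = pd.DataFrame(rows, index=list(ms.names), columns=e.sample_ids)
    return EigengeneMatrix(values, np.asarray(evr))


def write_eigengenes(eg: EigengeneMatrix, path) -> None:
    eg.values.to_csv(path, sep="\t", index_label="module", lineterminator="\n")


def read_eigengenes(path) -> EigengeneMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    return EigengeneMatrix(df, np.full(len(df), np.nan))


class EigengeneSummarizer(BaseEstimator, TransformerMixin):
    """Transformer mapping an expression matrix to its module eigengenes."""

    def __init__(self, modules: ModuleSet | None = None):
        self.modules = modules

    def fit(self, X: ExpressionMatrix, y=None):
        if self.modules is None:
            raise ValueError("modules must be provided")
        self.eigengenes_ = eigengenes(X, self.modules)
        return self

    def transform(self, X: ExpressionMatrix) -> EigengeneMatrix:
        return eigengenes(X, self.modules)
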