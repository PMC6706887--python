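"""Survival evaluation of patient stratifications and the DE filter.

Kaplan-Meier curves and the G-group log-rank test are delegated to
lifelines; the differential-expression filter runs per-gene Welch-free
two-sample t-tests on log2(x+1) values with a raw-scale fold-change gate and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

FOLDCHANGE_CUTOFF = 1.5
ADJ_P_CUTOFF = 1e-3


@dataclass
class SurvivalCurve:
    group: str
    event_times: np.ndarray       # ascending
    survival: np.ndarray          # product-limit estimate at each time
    at_risk: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.survival, dtype=float)
        if s.size and (np.diff(s) > 1e-12).any():
            raise ValueError("survival estimate must be non-increasing")


def kaplan_meier(times, events, groups) -> list[SurvivalCurve]:
    """Product-limit estimator per group.

    Tied event and censor times follow the standard convention: events are
    processed first, so a subject censored at t is still at risk for the
    event at t.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative times")
    curves = []
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        tab = kmf.event_table
        sf = kmf.survival_function_.iloc[:, 0].reindex(tab.index)
        times_g = tab.index.to_numpy(dtype=float)
        keep = times_g > 0
        curves.append(
            SurvivalCurve(
                group=str(g),
                event_times=times_g[keep],
                survival=sf.to_numpy()[keep],
                at_risk=tab["at_risk"].to_numpy()[keep],
            )
        )
    return curves


def logrank(times, events, groups) -> tuple[float, float]:
    """G-group log-rank chi-square (G-1 df) and its p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValueError("log-rank test requires >= 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class DEResult:
    table: pd.DataFrame  # index gene_id; columns log2fc, foldchange, p, p_adj, passed

    @property
    def passed_genes(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])


def differential_expression(e: ExpressionMatrix, group_a, group_b,
                            pseudocount: float = 1.0) -> DEResult:
    """Two-sided t-test on log2(x+1) with a raw-scale fold-change filter.

    Fold change is (mean_A + pseudocount) / (mean_B + pseudocount) on the raw
    scale; a gene passes with FC >= 1.5 or FC <= 1/1.5 and BH-adjusted
    p < 0.001.  Expects a raw non-negative (FPKM-like) matrix.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs >= 3 samples")
    if e.scale == "zscore":
        raise ValueError("differential expression expects raw-scale values")
    xa = e.values[group_a].to_numpy(dtype=float)
    xb = e.values[group_b].to_numpy(dtype=float)
    if (xa < 0).any() or (xb < 0).any():
        raise ValueError("raw expression must be non-negative")
    la, lb = np.log2(xa + 1.0), np.log2(xb + 1.0)
    tstat, p = stats.ttest_ind(la, lb, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    fc = (xa.mean(axis=1) + pseudocount) / (xb.mean(axis=1) + pseudocount)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    passed = ((fc >= FOLDCHANGE_CUTOFF) | (fc <= 1.0 / FOLDCHANGE_CUTOFF)) & (p_adj < ADJ_P_CUTOFF)
    table = pd.DataFrame(
        {
            "log2fc": np.log2(fc),
            "foldchange": fc,
            "p": p,
            "p_adj": p_adj,
            "passed": passed,
        },
        index=pd.Index(e.gene_ids, name="gene_id"),
    )
    return DEResult(table)


def km_table(curves: list[SurvivalCurve]) -> pd.DataFrame:
    """Long-form KM export: group, time, survival, at-risk."""
    frames = [
        pd.DataFrame(
            {"group": c.group, "time": c.event_times, "survival": c.survival,
             "at_risk": c.at_risk}
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)
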