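"""Differential expression: disease signatures and drug z-score profiles.

The disease stage calls DEGs with a two-sample t-test, Benjamini-Hochberg
adjustment across all tested genes, and a fold-change filter.  The drug
stage converts each gene's t statistic into a signed z-score through the
probability-integral transform z = Phi^-1(F_t(t; df)) and assigns
up/down regulation by the +/-1.96 rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from synsig.datatypes import (
    CLAMP_EPS,
    Z_THRESHOLD,
    DiseaseSignature,
    DrugZProfile,
    ExpressionDataset,
)

__all__ = ["disease_degs", "drug_zscores", "two_sample_t", "regulation_calls"]


def two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test of ``a`` vs ``b`` (genes x samples).

    Returns ``(t, p, df)``.  Degenerate rows (zero variance in both
    groups with equal means) yield t = 0, p = 1 rather than NaN; rows
    with zero variance but unequal means keep t = +/-inf, p = 0.
    """
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError(
            f"need >=2 samples per group, got {a.shape[1]} and {b.shape[1]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)
    degenerate = np.isnan(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    # Welch df is NaN for zero-variance rows; fall back to pooled df there
    df = np.where(np.isfinite(df), df, a.shape[1] + b.shape[1] - 2)
    return t, p, df


def disease_degs(
    data: ExpressionDataset,
    alpha_bh: float = 0.01,
    min_fold_change: float = 2.0,
    disease_id: str = "disease",
    equal_var: bool = True,
) -> DiseaseSignature:
    """Call disease DEGs: case vs control t-test, BH adjustment, and a
    fold-change filter of at least ``min_fold_change`` in either direction.

    On log2 data the fold-change rule is |mean_case - mean_control| >=
    log2(min_fold_change).  A gene is ``up`` if it passes both filters
    with a positive shift, ``down`` with a negative shift.
    """
    if min_fold_change < 1:
        raise ValueError("min_fold_change must be >= 1")
    case = data.group_matrix("case")
    control = data.group_matrix("control")
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError(
            f"disease data needs >=2 case and >=2 control samples, got "
            f"{case.shape[1]} case / {control.shape[1]} control"
        )
    t, p, _ = two_sample_t(case, control, equal_var=equal_var)
    p_adj = multipletests(p, method="fdr_bh")[1]
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    lfc_cut = np.log2(min_fold_change)

    sig = p_adj < alpha_bh
    up = sig & (log2fc >= lfc_cut)
    down = sig & (-log2fc >= lfc_cut)

    calls = pd.Series("", index=data.gene_ids, dtype=object)
    calls[up] = "up"
    calls[down] = "down"
    calls = calls[calls != ""]

    table = pd.DataFrame(
        {"t": t, "p": p, "p_adj": p_adj, "log2fc": log2fc}, index=data.gene_ids
    )
    return DiseaseSignature(
        disease_id=disease_id,
        calls=calls,
        alpha_bh=alpha_bh,
        min_fold_change=min_fold_change,
        stats=table,
    )


def t_to_z(t: np.ndarray, df: np.ndarray, eps: float = CLAMP_EPS) -> np.ndarray:
    """Map t statistics to signed z-scores, z = Phi^-1(F_t(t; df)).

    Computed from the upper tail of |t| so that z(-t) = -z(t) holds
    exactly in floating point; the tail probability is clamped at
    ``eps``, bounding |z| at about 7.94.
    """
    t = np.asarray(t, dtype=float)
    tail = stats.t.sf(np.abs(t), df)
    tail = np.clip(tail, eps, 1.0)
    return np.sign(t) * stats.norm.isf(tail)


def regulation_calls(z: pd.Series, threshold: float = Z_THRESHOLD) -> pd.Series:
    """up iff z > threshold, down iff z < -threshold, else none."""
    reg = pd.Series("none", index=z.index, dtype=object)
    reg[z > threshold] = "up"
    reg[z < -threshold] = "down"
    return reg


def drug_zscores(
    data: ExpressionDataset,
    treatment_id: str = "drug",
    equal_var: bool = True,
    z_threshold: float = Z_THRESHOLD,
    eps: float = CLAMP_EPS,
) -> DrugZProfile:
    """Per-gene signed z-scores for one drug (treated vs control)."""
    treated = data.group_matrix("treated")
    control = data.group_matrix("control")
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError(
            f"drug data needs >=2 treated and >=2 control samples, got "
            f"{treated.shape[1]} treated / {control.shape[1]} control"
        )
    t, _, df = two_sample_t(treated, control, equal_var=equal_var)
    # zero-variance unequal-means rows carry t = +/-inf; the clamp below
    # turns them into the maximal finite |z|
    z = t_to_z(np.where(np.isfinite(t), t, np.sign(t) * 1e30), df, eps=eps)
    z_series = pd.Series(z, index=data.gene_ids, name="z")
    return DrugZProfile(
        treatment_id=treatment_id,
        z=z_series,
        regulation=regulation_calls(z_series, threshold=z_threshold),
        t=pd.Series(t, index=data.gene_ids, name="t"),
    )
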