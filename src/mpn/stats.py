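"""Downstream group statistics and external-cohort projection.

Two-group means are compared with Welch's t test, multi-group means with
one-way ANOVA, and p-values are Bonferroni-adjusted for a caller-declared
family size.  The quartile contrast compares longitudinal MMSE decline
between the lowest- and highest-expression quartiles of a module or gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    test: str
    groups: list[str]
    statistic: float
    p_raw: float
    p_adjusted: float
    m: int
    group_means: dict = field(default_factory=dict)
    group_sizes: dict = field(default_factory=dict)


def _bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def group_compare(
    values,
    labels,
    family_size: int = 1,
    equal_var: bool = False,
) -> StatResult:
    """Welch t test (2 groups) or one-way ANOVA (>2 groups) on group means."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = sorted(pd.unique(labels).tolist())
    groups = [values[labels == name] for name in names]
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")
    for name, grp in zip(names, groups):
        if len(grp) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    if len(groups) == 2:
        stat, p = sps.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        test = "t" if equal_var else "welch_t"
    else:
        stat, p = sps.f_oneway(*groups)
        test = "anova_f"
    if np.isnan(p):  # all values identical in both groups
        stat, p = 0.0, 1.0
    return StatResult(
        test=test,
        groups=[str(n) for n in names],
        statistic=float(stat),
        p_raw=float(p),
        p_adjusted=_bonferroni(float(p), family_size),
        m=family_size,
        group_means={str(n): float(g.mean()) for n, g in zip(names, groups)},
        group_sizes={str(n): int(len(g)) for n, g in zip(names, groups)},
    )


def quartile_decline_contrast(
    expression,
    mmse_first,
    mmse_last,
    family_size: int = 1,
) -> StatResult:
    """Compare MMSE decline between extreme expression quartiles.

    Decline_i = mmse_first_i - mmse_last_i.  The low-expression group is
    below the empirical 25th percentile of expression, the high-expression
    group above the 75th (linear-interpolation percentiles; subjects
    exactly on a boundary go to the inner, non-extreme group).  Welch t
    test of decline between the two groups.
    """
    expression = np.asarray(expression, dtype=float)
    first = np.asarray(mmse_first, dtype=float)
    last = np.asarray(mmse_last, dtype=float)
    if not (len(expression) == len(first) == len(last)):
        raise ValueError("expression and MMSE vectors must be aligned")
    if len(expression) < 8:
        raise ValueError(f"need >= 8 subjects, got {len(expression)}")
    decline = first - last
    q25, q75 = np.percentile(expression, [25, 75])
    low = expression < q25
    high = expression > q75
    if not low.any() or not high.any():
        raise ValueError("an extreme quartile group is empty after ties")
    stat, p = sps.ttest_ind(decline[low], decline[high], equal_var=False)
    if np.isnan(p):
        stat, p = 0.0, 1.0
    return StatResult(
        test="welch_t",
        groups=["low_expression_q4", "high_expression_q1"],
        statistic=float(stat),
        p_raw=float(p),
        p_adjusted=_bonferroni(float(p), family_size),
        m=family_size,
        group_means={
            "low_expression_q4": float(decline[low].mean()),
            "high_expression_q1": float(decline[high].mean()),
        },
        group_sizes={
            "low_expression_q4": int(low.sum()),
            "high_expression_q1": int(high.sum()),
        },
    )


def project_eigengene(
    external: ExpressionMatrix,
    module_genes: list[str],
    reference_weights: pd.Series,
    min_overlap: float = 0.5,
) -> pd.Series:
    """Project external samples onto a reference module eigengene.

    The external matrix is z-scored per gene, then samples are projected
    onto the reference singular-vector gene weights restricted to the
    shared genes (weights renormalized to unit norm).  Requires at least
    ``min_overlap`` of the module genes to be present.
    """
    module_genes = list(module_genes)
    shared = [g for g in module_genes if g in external.gene_ids]
    overlap = len(shared) / len(module_genes)
    if overlap < min_overlap:
        missing = sorted(set(module_genes) - set(shared))
        raise ValueError(
            f"only {len(shared)}/{len(module_genes)} module genes present "
            f"({overlap:.0%} < {min_overlap:.0%}); missing e.g. {missing[:10]}"
        )
    if overlap < 1.0:
        logger.info("projecting with %d/%d module genes", len(shared), len(module_genes))
    sub = external.values.loc[shared].to_numpy(dtype=float)
    sub = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
    w = reference_weights.loc[shared].to_numpy(dtype=float)
    w = w / np.linalg.norm(w)
    proj = w @ sub
    norm = np.linalg.norm(proj)
    if norm > 0:
        proj = proj / norm
    return pd.Series(proj, index=external.sample_ids, name="projected_eigengene")
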