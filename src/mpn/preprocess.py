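"""Expression normalization, variance filtering, and phenotype labelling.

The reserve/loss-reserve classification operationalizes cognitive reserve:
a subject who stays cognitively intact (MMSE > 26) despite substantial
tangle pathology (Braak >= 3) is labelled ``reserve``; a subject with
MMSE < 26 has lost reserve.  Cognitively intact subjects without pathology
carry no information about reserve and are labelled ``not_evaluable``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    LOSS_RESERVE,
    NOT_EVALUABLE,
    RESERVE,
)

logger = logging.getLogger(__name__)


def zscore_normalize(matrix: ExpressionMatrix, drop_constant: bool = False) -> ExpressionMatrix:
    """Z-score every gene row (mean 0, sample sd 1 with denominator n-1).

    Constant rows are either dropped (``drop_constant=True``, logged) or
    raise an error naming the first offending gene.
    """
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        genes = values.index[constant].tolist()
        if not drop_constant:
            raise ValueError(f"zero-variance gene rows: {genes[:10]}")
        logger.info("dropping %d zero-variance genes: %s", len(genes), genes[:10])
        values = values.loc[~constant]
        sd = sd.loc[~constant]
    out = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(out, normalized=True)


def variance_filter(
    matrix: ExpressionMatrix,
    keep_fraction: float | None = 0.25,
    keep_count: int | None = None,
) -> ExpressionMatrix:
    """Retain the highest-standard-deviation genes.

    Exactly one of ``keep_fraction`` (ceil(fraction * n_genes) survivors) or
    ``keep_count`` (absolute survivor count) applies; ``keep_count`` wins if
    both are given.  Ties are broken by input order and the original row
    order is preserved among survivors.
    """
    n = matrix.n_genes
    if keep_count is not None:
        if not 0 < keep_count <= n:
            raise ValueError(f"keep_count must be in (0, {n}], got {keep_count}")
        k = int(keep_count)
    else:
        if keep_fraction is None or not 0 < keep_fraction <= 1:
            raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
        k = math.ceil(keep_fraction * n)
    sd = matrix.values.std(axis=1, ddof=1).to_numpy()
    # stable argsort on -sd: earlier rows win ties
    order = np.argsort(-sd, kind="stable")[:k]
    keep = np.zeros(n, dtype=bool)
    keep[order] = True
    logger.info("variance filter kept %d of %d genes", k, n)
    return ExpressionMatrix(matrix.values.loc[keep], normalized=matrix.normalized)


def classify_reserve(
    phenotypes: pd.DataFrame,
    borderline_braak_min: int = 3,
) -> pd.DataFrame:
    """Assign reserve labels from MMSE and Braak stage.

    Rules: ``reserve`` if MMSE > 26 and Braak >= 3; ``loss_reserve`` if
    MMSE < 26; borderline MMSE = 26 resolved by pathology (reserve iff
    Braak >= ``borderline_braak_min``); MMSE > 26 with Braak < 3 is
    ``not_evaluable`` (intact cognition without pathology says nothing
    about reserve).  Returns a copy with a ``reserve_label`` column.
    """
    for col in ("mmse", "braak"):
        if col not in phenotypes:
            raise ValueError(f"phenotype table lacks required column '{col}'")
        missing = phenotypes.index[phenotypes[col].isna()].tolist()
        if missing:
            raise ValueError(f"missing {col} for samples: {missing}")
    mmse = phenotypes["mmse"]
    braak = phenotypes["braak"]
    label = pd.Series(NOT_EVALUABLE, index=phenotypes.index, dtype=object)
    label[(mmse > 26) & (braak >= 3)] = RESERVE
    label[mmse < 26] = LOSS_RESERVE
    border = mmse == 26
    label[border & (braak >= borderline_braak_min)] = RESERVE
    label[border & (braak < borderline_braak_min)] = LOSS_RESERVE
    out = phenotypes.copy()
    out["reserve_label"] = label
    counts = label.value_counts().to_dict()
    logger.info("reserve labels: %s", counts)
    return out


_SEVERITY_BINS = (
    # (name, lower inclusive, upper inclusive); control/severe open-ended
    ("severe", -np.inf, 13),
    ("moderate", 14, 19),
    ("incipient", 20, 25),
    ("control", 26, np.inf),
)


def severity_groups(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Bin MMSE into severity groups.

    control: MMSE > 25; incipient: 20-25; moderate: 14-19; severe: < 14.
    The bins assume integer MMSE; a non-integer score falling in the gap
    between two bins (e.g. 19.5) raises, demanding an explicit rounding
    policy upstream.
    """
    if "mmse" not in phenotypes:
        raise ValueError("phenotype table lacks required column 'mmse'")
    mmse = phenotypes["mmse"].to_numpy(dtype=float)
    group = np.full(mmse.shape, None, dtype=object)
    # open-ended bins tolerate non-integers; the gap (19, 20) does not
    group[mmse < 14] = "severe"
    group[(mmse >= 14) & (mmse <= 19)] = "moderate"
    group[(mmse >= 20) & (mmse <= 25)] = "incipient"
    group[mmse > 25] = "control"
    unassigned = group == None  # noqa: E711 -- elementwise on object array
    if unassigned.any():
        bad = phenotypes.index[unassigned].tolist()
        vals = mmse[unassigned].tolist()
        raise ValueError(
            f"non-integer MMSE between severity bins for samples {bad} "
            f"(values {vals}); apply an explicit rounding policy first"
        )
    out = phenotypes.copy()
    out["diagnosis_group"] = group
    return out


_SEX_CODES = {"male": 0.0, "female": 1.0}
_SEVERITY_CODES = {"control": 0.0, "incipient": 1.0, "moderate": 2.0, "severe": 3.0}


def encode_traits(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Numerically encode phenotypes for correlation and network scoring.

    sex -> 0/1 (male/female); diagnosis_group -> ordinal 0..3 by severity;
    reserve_label -> 1 for reserve, 0 otherwise.  Numeric columns pass
    through unchanged.
    """
    out = pd.DataFrame(index=phenotypes.index)
    for col in phenotypes.columns:
        if col == "sex":
            out["sex"] = phenotypes["sex"].map(_SEX_CODES).astype(float)
        elif col == "diagnosis_group":
            out["diagnosis"] = phenotypes["diagnosis_group"].map(_SEVERITY_CODES).astype(float)
        elif col == "reserve_label":
            out["reserve"] = (phenotypes["reserve_label"] == RESERVE).astype(float)
        else:
            out[col] = pd.to_numeric(phenotypes[col])
    return out
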