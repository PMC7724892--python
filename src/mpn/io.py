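"""Readers and writers for the pipeline's tabular and graph formats.

All tables are UTF-8 tab-separated text: expression as genes x samples with
a header row of sample ids, phenotypes as one row per sample, networks as
(from, to, frequency) edge lists.  Networks are additionally exported as
GraphML for graph viewers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_phenotypes

logger = logging.getLogger(__name__)

_SEX_ALIASES = {"m": "male", "male": "male", "f": "female", "female": "female"}


def _check_rectangular(path: Path) -> None:
    width = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            n = line.rstrip("\n").count("\t") + 1
            if width is None:
                width = n
            elif n != width:
                raise ValueError(
                    f"{path}: line {lineno} has {n} fields, expected {width}"
                )


def read_expression(path, missing_policy: str = "drop") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header of sample ids).

    Duplicate gene ids raise with the offending id and line number.  Rows
    with missing cells are dropped and logged (``missing_policy='drop'``)
    or raise (``'error'``).
    """
    path = Path(path)
    _check_rectangular(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: malformed expression table: {exc}") from exc
    if df.columns.size == 0:
        raise ValueError(f"{path}: malformed header, no sample columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()]
        first = dup[0]
        line = int(np.where(df.index == first)[0][1]) + 2  # + header line
        raise ValueError(f"{path}: duplicate gene id {first!r} at line {line}")
    missing = df.isna().any(axis=1)
    if missing.any():
        if missing_policy == "error":
            raise ValueError(
                f"{path}: missing values in genes {df.index[missing].tolist()[:10]}"
            )
        logger.info("%s: dropping %d genes with missing cells", path, int(missing.sum()))
        df = df.loc[~missing]
    return ExpressionMatrix(df.astype(float))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.10g")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a per-sample phenotype TSV (requires mmse and braak columns).

    Sex strings {M, F, male, female} (case-insensitive) are normalized;
    MMSE and Braak are range-checked.
    """
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("mmse", "braak"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column '{col}' missing")
    if "sex" in df.columns:
        normalized = df["sex"].astype(str).str.strip().str.lower().map(_SEX_ALIASES)
        bad = df.index[df["sex"].notna() & normalized.isna()].tolist()
        if bad:
            raise ValueError(f"{path}: unrecognized sex values for samples {bad}")
        df["sex"] = normalized
    return validate_phenotypes(df)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t")


def read_partition(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(int)


def write_partition(labels: pd.Series, path) -> None:
    labels.rename("module").to_frame().to_csv(path, sep="\t")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_network(graph, path_tsv, path_graphml=None) -> None:
    """Write a directed or undirected graph as an edge-list TSV (+ GraphML)."""
    rows = [
        {"from": u, "to": v, "frequency": attrs.get("frequency", 1.0)}
        for u, v, attrs in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["from", "to", "frequency"]).to_csv(
        path_tsv, sep="\t", index=False, float_format="%.10g"
    )
    if path_graphml is not None:
        nx.write_graphml(graph, path_graphml)


def read_network(path_tsv, directed: bool = True):
    df = pd.read_csv(path_tsv, sep="\t")
    graph = nx.DiGraph() if directed else nx.Graph()
    for _, row in df.iterrows():
        graph.add_edge(row["from"], row["to"], frequency=float(row["frequency"]))
    return graph
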