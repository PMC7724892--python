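"""Weighted co-expression network core.

Implements the unsigned WGCNA chain: Pearson similarity, soft-threshold
selection by scale-free topology fit, power adjacency a_ij = |cor_ij|^beta,
topological overlap TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
with l_ij = sum_u a_iu a_uj, average-linkage clustering on 1 - TOM with a
fixed-height cut, module eigengenes (first principal component of the
standardized module submatrix), and covariate-adjusted module-trait
statistics with Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, ModulePartition

logger = logging.getLogger(__name__)


def pearson_similarity(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene-gene Pearson correlation matrix (symmetric, unit diagonal)."""
    if matrix.n_samples < 3:
        raise ValueError("at least 3 samples required for correlation")
    sd = matrix.values.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = matrix.gene_ids[sd == 0].tolist()
        raise ValueError(f"constant gene rows (drop upstream): {bad[:10]}")
    cor = np.corrcoef(matrix.values.to_numpy())
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=matrix.gene_ids, columns=matrix.gene_ids)


def adjacency(sim: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned power adjacency a_ij = |cor_ij|^beta."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    return np.abs(sim) ** beta


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Node connectivity k_i = sum_{j != i} a_ij (diagonal excluded)."""
    a = adj.to_numpy(copy=True)
    np.fill_diagonal(a, 0.0)
    return pd.Series(a.sum(axis=1), index=adj.index, name="k")


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins k into ``n_bins`` equal-width bins, regresses log10(frequency) on
    log10(mean k) over the nonempty bins and returns (signed R^2, slope).
    The R^2 is negated for positive slopes so that only decreasing degree
    distributions can score highly.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        raise ValueError("fewer than 3 nonempty connectivity bins")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    keep = freq > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 nonempty connectivity bins")
    mean_k = np.array(
        [k[idx == b].mean() if freq[b] else np.nan for b in range(n_bins)]
    )
    x, y = np.log10(mean_k[keep]), np.log10(freq[keep] / freq.sum())
    res = sps.linregress(x, y)
    r2 = res.rvalue**2
    return (-r2 if res.slope > 0 else r2), res.slope


@dataclass
class SoftThresholdResult:
    beta: int
    fit_table: pd.DataFrame  # power, r_squared, slope, mean_k
    warning: bool = False


def pick_soft_threshold(
    sim: pd.DataFrame,
    candidate_powers: tuple[int, ...] = tuple(range(1, 21)),
    r2_cutoff: float = 0.9,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Choose the smallest power whose scale-free fit reaches ``r2_cutoff``.

    Falls back to the argmax-R^2 power with ``warning=True`` when no
    candidate reaches the cutoff.
    """
    if not candidate_powers:
        raise ValueError("candidate_powers must be nonempty")
    rows = []
    for power in candidate_powers:
        k = connectivity(adjacency(sim, power)).to_numpy()
        try:
            r2, slope = scale_free_fit(k, n_bins=n_bins)
        except ValueError:  # degenerate connectivity at this power
            r2, slope = -np.inf, np.nan
        rows.append({"power": power, "r_squared": r2, "slope": slope,
                     "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    if not np.isfinite(table["r_squared"]).any():
        raise ValueError("scale-free fit degenerate at every candidate power")
    passing = table[table["r_squared"] >= r2_cutoff]
    if len(passing):
        beta = int(passing.iloc[0]["power"])
        return SoftThresholdResult(beta, table, warning=False)
    beta = int(table.loc[table["r_squared"].idxmax(), "power"])
    logger.warning("no power reached R^2 >= %.2f; falling back to %d", r2_cutoff, beta)
    return SoftThresholdResult(beta, table, warning=True)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j with
    l_ij = sum_u a_iu a_uj over u != i, j; TOM_ii = 1 by convention.
    """
    a = adj.to_numpy(copy=True).astype(float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a
    num = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    t = num / den
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def cluster_modules(
    tom_matrix: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.998,
) -> ModulePartition:
    """Detect modules by average-linkage clustering of the TOM dissimilarity.

    The dendrogram on 1 - TOM is cut at ``cut_height``; clusters smaller
    than ``min_module_size`` fall into the grey pool (label 0); surviving
    modules are relabelled 1..K by decreasing size.
    """
    if min_module_size < 2:
        raise ValueError(f"min_module_size must be >= 2, got {min_module_size}")
    diss = 1.0 - tom_matrix.to_numpy()
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    counts = pd.Series(raw).value_counts()
    big = counts[counts >= min_module_size].index
    # relabel by decreasing size; ties by original cluster id for determinism
    order = sorted(big, key=lambda c: (-counts[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([relabel.get(c, 0) for c in raw])
    if labels.max() == 0:
        logger.warning("no module reached min_module_size=%d; all genes grey",
                       min_module_size)
    return ModulePartition(
        pd.Series(labels, index=tom_matrix.index, name="module"),
        min_module_size=2,
    )


@dataclass
class ModuleEigengenes:
    """Per-module eigengenes and the gene weights that produce them.

    ``eigengenes`` is modules x samples with unit-Euclidean-norm rows,
    sign-aligned so each eigengene correlates nonnegatively with its
    module's mean expression profile.  ``gene_weights`` holds the left
    singular vector (per-gene loadings) used for projection into external
    cohorts.
    """

    eigengenes: pd.DataFrame
    variance_explained: pd.Series
    gene_weights: dict[int, pd.Series] = field(default_factory=dict)


def module_eigengenes(
    matrix: ExpressionMatrix, partition: ModulePartition
) -> ModuleEigengenes:
    """First principal component of each module's standardized submatrix."""
    if not partition.module_labels:
        raise ValueError("partition contains no modules")
    values = matrix.values
    rows, var_exp, weights = {}, {}, {}
    for label in partition.module_labels:
        genes = partition.genes_in(label)
        sub = values.loc[genes].to_numpy()
        sub = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
        if len(genes) == 1:
            logger.warning("module %d has a single gene; eigengene = its profile", label)
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        me, w = vt[0], u[:, 0]
        mean_profile = sub.mean(axis=0)
        if np.dot(me, mean_profile - mean_profile.mean()) < 0:
            me, w = -me, -w
        name = f"M{label}"
        rows[name] = me
        var_exp[name] = float(s[0] ** 2 / (s**2).sum())
        weights[label] = pd.Series(w, index=genes, name=name)
    eig = pd.DataFrame(rows, index=matrix.sample_ids).T
    return ModuleEigengenes(eig, pd.Series(var_exp, name="variance_explained"), weights)


@dataclass
class ModuleTraitResult:
    correlation: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n_tests: int


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), covariates])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    covariates: list[str] | None = None,
) -> ModuleTraitResult:
    """Partial Pearson correlation of eigengenes with traits.

    Both sides are residualized on the covariate columns (least squares
    with intercept) before correlating; p-values use the t transform with
    n - 2 - #covariates degrees of freedom; Bonferroni adjustment spans the
    full module x trait grid.
    """
    covariates = covariates or []
    samples = eigengenes.columns
    trait_cols = [c for c in traits.columns if c not in covariates]
    cov = traits.loc[samples, covariates].to_numpy(dtype=float) if covariates else None
    n = len(samples)
    df = n - 2 - len(covariates)
    if df < 1:
        raise ValueError(f"not enough samples ({n}) for {len(covariates)} covariates")
    cor = pd.DataFrame(index=eigengenes.index, columns=trait_cols, dtype=float)
    p = pd.DataFrame(index=eigengenes.index, columns=trait_cols, dtype=float)
    for trait in trait_cols:
        t_raw = traits.loc[samples, trait].to_numpy(dtype=float)
        t_res = _residualize(t_raw, cov) if covariates else t_raw - t_raw.mean()
        if np.std(t_res) < 1e-12:
            raise ValueError(
                f"trait '{trait}' is collinear with covariates {covariates}"
            )
        for module in eigengenes.index:
            e_raw = eigengenes.loc[module].to_numpy(dtype=float)
            e_res = _residualize(e_raw, cov) if covariates else e_raw - e_raw.mean()
            r = float(np.corrcoef(e_res, t_res)[0, 1])
            r = float(np.clip(r, -1.0, 1.0))
            cor.loc[module, trait] = r
            if abs(r) >= 1.0:
                p.loc[module, trait] = 0.0
            else:
                tstat = r * np.sqrt(df / (1.0 - r**2))
                p.loc[module, trait] = float(2.0 * sps.t.sf(abs(tstat), df))
    m = int(cor.size)
    p_adj = np.minimum(1.0, p * m)
    return ModuleTraitResult(cor, p, p_adj, m)


@dataclass
class GeneTraitResult:
    gene_significance: pd.Series          # |cor(gene, trait)|
    module_membership: pd.DataFrame       # genes x modules, cor(gene, ME)
    module_mm_gs_cor: pd.DataFrame        # per module: cor(MM, GS), p


def gene_significance_and_membership(
    matrix: ExpressionMatrix,
    eigengenes: pd.DataFrame,
    trait: pd.Series,
    partition: ModulePartition | None = None,
) -> GeneTraitResult:
    """Gene significance (GS) and module membership (MM) statistics.

    GS_g = |cor(x_g, trait)|; MM_{g,m} = cor(x_g, ME_m).  When a partition
    is given, cor(MM, GS) with its p-value is reported within each module.
    """
    x = matrix.values.to_numpy()
    t = trait.loc[matrix.sample_ids].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    xs = xc / np.linalg.norm(xc, axis=1, keepdims=True)
    tc = t - t.mean()
    ts = tc / np.linalg.norm(tc)
    gs = pd.Series(np.abs(xs @ ts), index=matrix.gene_ids, name="GS")
    e = eigengenes.to_numpy()
    ec = e - e.mean(axis=1, keepdims=True)
    es = ec / np.linalg.norm(ec, axis=1, keepdims=True)
    mm = pd.DataFrame(xs @ es.T, index=matrix.gene_ids, columns=eigengenes.index)
    rows = []
    if partition is not None:
        for label in partition.module_labels:
            genes = partition.genes_in(label)
            name = f"M{label}"
            if name not in mm.columns or len(genes) < 3:
                continue
            r, pval = sps.pearsonr(np.abs(mm.loc[genes, name]), gs.loc[genes])
            rows.append({"module": name, "cor_mm_gs": r, "p": pval,
                         "n_genes": len(genes)})
    table = pd.DataFrame(rows, columns=["module", "cor_mm_gs", "p", "n_genes"])
    return GeneTraitResult(gs, mm, table)
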