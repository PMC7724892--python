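"""Synthetic cohorts with planted co-expression modules and driven phenotypes.

The generator emulates a small post-mortem hippocampal microarray cohort:
a few thousand retained genes organised into ~11 latent co-expression
modules, with one module causally coupled to cognition and pathology.
Each module m carries a standard-normal latent factor f_m per sample and
gene g in module m is

    x_g = loading_g * f_m + noise_sd * eps_g,

so eigengene recovery, module-trait correlation, Bayesian-network
prioritization, and hub-gene ranking all have a known ground truth.
Phenotypes follow the causal module's factor f_c:

    pathology = -rho * f_c + sqrt(1 - rho^2) * eps      (standard normal)
    burden    = pathology + shift                       (shift 1.0: aged
                autopsy cohorts carry near-universal tangle pathology)
    Braak     = burden cut at the standard-normal septiles
    NFT       = round(exp(1.0 + 0.8 * burden + 0.4 * eps))
    MMSE      = clip(round(22 + 4 * (gamma * f_c - delta * pathology
                                      + sigma_m * eps)), 0, 30)

Age, sex, and PMI are independent nuisance covariates.  Reserve labels and
severity groups are derived by applying the preprocessing classifiers to
the generated MMSE/Braak, so the labels always satisfy the classification
rules by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix
from .preprocess import classify_reserve, severity_groups

#: default module sizes (sum 2993 of 3000 genes); the smallest module is the
#: causal one so its designated hub gene is an unambiguous, tractable
#: recovery target for the gene-level network stage
DEFAULT_MODULE_SIZES = (853, 560, 420, 310, 262, 190, 140, 100, 70, 50, 38)
DEFAULT_CAUSAL_INDEX = 10


class ConfigError(ValueError):
    """Raised when a synthetic-cohort configuration is invalid."""


@dataclass
class SyntheticConfig:
    """Parameters of the planted-module cohort generator.

    Defaults mirror the emulated cohort: 31 samples, 3000 retained genes,
    11 modules spanning 38-853 genes.  ``gamma_mmse`` is the effect of the
    causal factor on the MMSE latent in standardized units;
    ``pathology_coupling`` (rho) couples the pathology latent negatively to
    the causal factor; ``pathology_mmse_weight`` (delta) is the direct
    pathology burden on cognition.  ``hub_loading`` sits above the sibling
    loading range so the designated hub gene is a statistically
    identifiable recovery target, not merely the argmax of an i.i.d. draw.
    """

    n_samples: int = 31
    n_genes: int = 3000
    module_sizes: tuple[int, ...] | None = None
    causal_module_index: int = DEFAULT_CAUSAL_INDEX
    loading_range: tuple[float, float] = (0.4, 0.9)
    gamma_mmse: float = 0.7
    noise_sd: float = 0.75
    hub_loading: float = 1.2
    pathology_coupling: float = 0.5
    pathology_shift: float = 1.0
    pathology_mmse_weight: float = 0.2
    mmse_noise_sd: float = 0.8
    mmse_baseline: float = 22.0
    mmse_scale: float = 4.0
    seed: int = 0

    def resolved_module_sizes(self) -> tuple[int, ...]:
        if self.module_sizes is not None:
            return tuple(int(s) for s in self.module_sizes)
        scale = self.n_genes / 3000
        sizes = [max(2, int(round(s * scale))) for s in DEFAULT_MODULE_SIZES]
        while sum(sizes) > self.n_genes:  # trim the largest on rounding overflow
            sizes[int(np.argmax(sizes))] -= 1
        return tuple(sizes)

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ConfigError(f"n_samples must be >= 4, got {self.n_samples}")
        if self.n_genes < 2:
            raise ConfigError(f"n_genes must be >= 2, got {self.n_genes}")
        sizes = self.resolved_module_sizes()
        if any(s < 2 for s in sizes):
            raise ConfigError(f"module_sizes must all be >= 2, got {sizes}")
        if sum(sizes) > self.n_genes:
            raise ConfigError(
                f"module_sizes sum {sum(sizes)} exceeds n_genes={self.n_genes}"
            )
        if not 0 <= self.causal_module_index < len(sizes):
            raise ConfigError(
                f"causal_module_index {self.causal_module_index} outside "
                f"0..{len(sizes) - 1}"
            )
        lo, hi = self.loading_range
        if not (0 < lo <= hi):
            raise ConfigError(f"loading_range must satisfy 0 < lo <= hi, got {self.loading_range}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be positive, got {self.noise_sd}")
        if not 0 <= self.pathology_coupling < 1:
            raise ConfigError(
                f"pathology_coupling must be in [0, 1), got {self.pathology_coupling}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``module_assignment`` maps each gene id to its planted module label
    (1..K, 0 for pure-noise genes); ``causal_module`` is the label of the
    phenotype-driving module; ``hub_gene`` is the designated maximal-loading
    gene inside it; ``factor_values`` holds the latent module factors
    (samples x modules); ``loadings`` the per-gene factor loadings.
    """

    module_assignment: pd.Series
    causal_module: int
    hub_gene: str
    factor_values: pd.DataFrame
    loadings: pd.Series
    phenotype_coefficients: dict = field(default_factory=dict)


#: equal-probability standard-normal cut points for the 7 Braak stages
_BRAAK_CUTS = sps.norm.ppf(np.arange(1, 7) / 7.0)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate an expression matrix, phenotype table, and ground truth.

    Deterministic given ``config.seed``.  Genes not covered by
    ``module_sizes`` are pure noise (module label 0).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = config.resolved_module_sizes()
    n, g = config.n_samples, config.n_genes
    n_modules = len(sizes)
    lo, hi = config.loading_range
    hub_loading = config.hub_loading

    gene_ids = pd.Index([f"G{i:04d}" for i in range(g)], name="gene_id")
    sample_ids = pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id")

    factors = rng.standard_normal((n_modules, n))
    loadings = np.zeros(g)
    assignment = np.zeros(g, dtype=int)
    values = np.empty((g, n))
    start = 0
    hub_gene = None
    for m, size in enumerate(sizes):
        stop = start + size
        load = rng.uniform(lo, hi, size=size)
        if m == config.causal_module_index:
            load[0] = hub_loading
            hub_gene = gene_ids[start]
        loadings[start:stop] = load
        assignment[start:stop] = m + 1
        values[start:stop] = (
            load[:, None] * factors[m]
            + config.noise_sd * rng.standard_normal((size, n))
        )
        start = stop
    if start < g:  # unassigned genes: pure noise at matched marginal scale
        values[start:] = config.noise_sd * rng.standard_normal((g - start, n))

    f_c = factors[config.causal_module_index]
    rho = config.pathology_coupling
    pathology = -rho * f_c + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    # aged autopsy cohorts carry near-universal tangle burden: the Braak/NFT
    # latent is location-shifted so high stages dominate
    burden = pathology + config.pathology_shift
    braak = np.digitize(burden, _BRAAK_CUTS)
    nft = np.round(np.exp(1.0 + 0.8 * burden + 0.4 * rng.standard_normal(n)))
    mmse_latent = (
        config.gamma_mmse * f_c
        - config.pathology_mmse_weight * pathology
        + config.mmse_noise_sd * rng.standard_normal(n)
    )
    mmse = np.clip(
        np.round(config.mmse_baseline + config.mmse_scale * mmse_latent), 0, 30
    )

    pheno = pd.DataFrame(
        {
            "mmse": mmse,
            "braak": braak,
            "nft": nft,
            "age": np.clip(np.round(rng.normal(80, 7, size=n)), 60, 100),
            "sex": rng.choice(["male", "female"], size=n),
            "pmi": np.round(np.clip(rng.normal(6, 2, size=n), 1, None), 1),
        },
        index=sample_ids,
    )
    pheno = severity_groups(classify_reserve(pheno))

    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    truth = SyntheticTruth(
        module_assignment=pd.Series(assignment, index=gene_ids, name="module"),
        causal_module=config.causal_module_index + 1,
        hub_gene=str(hub_gene),
        factor_values=pd.DataFrame(
            factors.T, index=sample_ids,
            columns=[f"M{m + 1}" for m in range(n_modules)],
        ),
        loadings=pd.Series(loadings, index=gene_ids, name="loading"),
        phenotype_coefficients={
            "gamma_mmse": config.gamma_mmse,
            "pathology_coupling": rho,
            "pathology_mmse_weight": config.pathology_mmse_weight,
        },
    )
    return matrix, pheno, truth


def generate_dag_data(
    dag: nx.DiGraph,
    coefficients: dict[tuple[str, str], float],
    noise_sd: float = 1.0,
    n: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a linear-Gaussian structural model along a DAG.

    Each node equals the coefficient-weighted sum of its parents plus
    ``noise_sd`` Gaussian noise, sampled in topological order.  Columns are
    named by node.  Raises on cyclic graphs or missing arc coefficients.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("graph is cyclic; a DAG is required")
    missing = [e for e in dag.edges if e not in coefficients]
    if missing:
        raise ValueError(f"arcs without coefficients: {missing}")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(dag):
        col = noise_sd * rng.standard_normal(n)
        for parent in dag.predecessors(node):
            col = col + coefficients[(parent, node)] * data[parent]
        data[node] = col
    return pd.DataFrame({node: data[node] for node in dag.nodes})
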