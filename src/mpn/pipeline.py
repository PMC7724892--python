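"""End-to-end pipeline driver: preprocess -> modules -> MPN -> hubs -> stats.

A single global seed is expanded into per-stage child seeds through a
counter scheme (stage index mixed into a ``SeedSequence``), so each stage
is reproducible independently of the others.  A JSON run manifest records
the package version, full parameter set, stage seeds, and SHA-256 digests
of all inputs and outputs; replaying a manifest's config reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as mpn_io
from .bayesnet import learn_averaged_network, prioritize_modules
from .coexpression import (
    ModuleEigengenes,
    adjacency,
    cluster_modules,
    module_eigengenes,
    module_trait_correlation,
    pearson_similarity,
    pick_soft_threshold,
    tom,
)
from .containers import ExpressionMatrix, LOSS_RESERVE, ModulePartition, RESERVE
from .hubgenes import EPCScores, build_gene_network, epc_score, select_hubs
from .preprocess import encode_traits, variance_filter, zscore_normalize
from .stats import group_compare

logger = logging.getLogger(__name__)

_PHENO_NODES = ("reserve", "mmse", "braak", "nft")


@dataclass
class PipelineConfig:
    """All pipeline parameters; unknown keys in a JSON config are rejected."""

    expression: str | None = None
    phenotypes: str | None = None
    outdir: str | None = None
    # preprocess
    keep_fraction: float | None = 0.25
    keep_count: int | None = None
    drop_constant: bool = True
    # coexpression
    beta: int | None = None  # None: pick by scale-free fit
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    r2_cutoff: float = 0.9
    cut_height: float = 0.998
    min_module_size: int = 30
    covariates: tuple[str, ...] = ("age", "sex", "pmi")
    # module-level Bayesian network
    n_restarts: int = 200
    arc_threshold: float = 0.5
    init_arc_prob: float = 0.1
    # gene-level network and hubs
    gene_n_restarts: int = 20
    gene_init_arc_prob: float = 0.02
    epc_p: float = 0.5
    epc_samples: int = 1000
    k_hubs: int = 6
    keep_genes: str | None = None
    # global seed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.keep_fraction is not None and not 0 < self.keep_fraction <= 1:
            raise ValueError(f"keep_fraction must be in (0, 1], got {self.keep_fraction}")
        if not 0 < self.arc_threshold <= 1:
            raise ValueError(f"arc_threshold must be in (0, 1], got {self.arc_threshold}")
        if not 0 < self.epc_p < 1:
            raise ValueError(f"epc_p must be in (0, 1), got {self.epc_p}")
        if self.n_restarts < 1 or self.gene_n_restarts < 1:
            raise ValueError("restart counts must be >= 1")
        if self.k_hubs < 1:
            raise ValueError(f"k_hubs must be >= 1, got {self.k_hubs}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("candidate_powers", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["candidate_powers"] = list(self.candidate_powers)
        d["covariates"] = list(self.covariates)
        return d


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Child seed for a pipeline stage (counter scheme, < 2**31)."""
    ss = np.random.SeedSequence([int(global_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    partition: ModulePartition
    eigengenes: ModuleEigengenes
    module_trait: pd.DataFrame
    soft_threshold: pd.DataFrame | None
    beta: int
    mpn_dag: nx.DiGraph
    mpn_strength: pd.DataFrame
    prioritization: pd.DataFrame
    top_module: str
    gene_network: nx.Graph
    epc: EPCScores
    hubs: list[str]
    hub_subnetwork: nx.Graph
    stats: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _module_trait_long(result) -> pd.DataFrame:
    rows = []
    for module in result.correlation.index:
        for trait in result.correlation.columns:
            rows.append(
                {
                    "module": module,
                    "trait": trait,
                    "cor": result.correlation.loc[module, trait],
                    "p_raw": result.p_raw.loc[module, trait],
                    "p_adjusted": result.p_adjusted.loc[module, trait],
                    "m": result.n_tests,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    phenotypes: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full module-to-phenotype pipeline.

    Inputs come either from ``config.expression`` / ``config.phenotypes``
    paths or directly as in-memory objects.  When ``config.outdir`` is set
    every product is written there along with ``manifest.json``.
    """
    stage = "input"
    try:
        input_digests = {}
        if matrix is None:
            if config.expression is None:
                raise ValueError("no expression input (config.expression or matrix)")
            input_digests["expression"] = _sha256(Path(config.expression))
            matrix = mpn_io.read_expression(config.expression)
        if phenotypes is None:
            if config.phenotypes is None:
                raise ValueError("no phenotype input (config.phenotypes or phenotypes)")
            input_digests["phenotypes"] = _sha256(Path(config.phenotypes))
            phenotypes = mpn_io.read_phenotypes(config.phenotypes)
        phenotypes = phenotypes.loc[matrix.sample_ids]

        stage = "preprocess"
        if not matrix.normalized:
            matrix = zscore_normalize(matrix, drop_constant=config.drop_constant)
        matrix = variance_filter(
            matrix, keep_fraction=config.keep_fraction, keep_count=config.keep_count
        )

        stage = "coexpression"
        sim = pearson_similarity(matrix)
        fit_table = None
        if config.beta is None:
            picked = pick_soft_threshold(
                sim, config.candidate_powers, r2_cutoff=config.r2_cutoff
            )
            beta, fit_table = picked.beta, picked.fit_table
        else:
            beta = int(config.beta)
        tom_matrix = tom(adjacency(sim, beta))
        partition = cluster_modules(
            tom_matrix,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
        )
        if not partition.module_labels:
            raise RuntimeError("no modules detected; adjust cut_height/min_module_size")
        eig = module_eigengenes(matrix, partition)
        traits = encode_traits(phenotypes)
        trait_cols = [c for c in ("mmse", "braak", "nft", "reserve", "diagnosis")
                      if c in traits.columns]
        covars = [c for c in config.covariates if c in traits.columns]
        mt = module_trait_correlation(
            eig.eigengenes, traits[trait_cols + covars], covariates=covars
        )

        stage = "mpn"
        mpn_data = eig.eigengenes.T.copy()
        for col in _PHENO_NODES:
            if col not in traits.columns:
                raise RuntimeError(f"phenotype column '{col}' required for the MPN")
            mpn_data[col] = traits[col]
        mpn_data = (mpn_data - mpn_data.mean()) / mpn_data.std(ddof=1)
        mpn_dag, strength = learn_averaged_network(
            mpn_data,
            n_restarts=config.n_restarts,
            arc_threshold=config.arc_threshold,
            seed=stage_seed(config.seed, 1),
            init_arc_prob=config.init_arc_prob,
        )
        ranking = prioritize_modules(
            mpn_dag, strength, module_nodes=list(eig.eigengenes.index),
            phenotype_nodes=_PHENO_NODES,
        )
        top_module = str(ranking.iloc[0]["module"])

        stage = "hubgenes"
        top_label = int(top_module.lstrip("M"))
        module_genes = partition.genes_in(top_label).tolist()
        keep = None
        if config.keep_genes:
            keep = [
                line.strip()
                for line in Path(config.keep_genes).read_text().splitlines()
                if line.strip()
            ]
        gene_net = build_gene_network(
            matrix,
            module_genes,
            keep_genes=keep,
            n_restarts=config.gene_n_restarts,
            arc_threshold=config.arc_threshold,
            seed=stage_seed(config.seed, 2),
            init_arc_prob=config.gene_init_arc_prob,
        )
        epc = epc_score(
            gene_net, p=config.epc_p, n_samples=config.epc_samples,
            seed=stage_seed(config.seed, 3),
        )
        k = min(config.k_hubs, max(1, len(epc.scores)))
        if len(epc.scores) == 0:
            raise RuntimeError("gene network is empty; no hubs to select")
        hubs, subnet = select_hubs(epc, gene_net, k=k)

        stage = "validation_stats"
        stats_rows = []
        me_top = eig.eigengenes.loc[top_module]
        labels = phenotypes["reserve_label"]
        evaluable = labels.isin([RESERVE, LOSS_RESERVE])
        tests = []
        if evaluable.sum() >= 4 and labels[evaluable].nunique() == 2 and \
                labels[evaluable].value_counts().min() >= 2:
            tests.append(("reserve_contrast", me_top[evaluable], labels[evaluable]))
        groups = phenotypes["diagnosis_group"]
        big_groups = groups.value_counts()
        usable = groups.isin(big_groups[big_groups >= 2].index)
        if big_groups[big_groups >= 2].size >= 2:
            tests.append(("severity_groups", me_top[usable], groups[usable]))
        m = len(tests)
        for name, values, labs in tests:
            res = group_compare(values.to_numpy(), labs.to_numpy(), family_size=m)
            stats_rows.append(
                {
                    "test": name,
                    "method": res.test,
                    "groups": "|".join(res.groups),
                    "statistic": res.statistic,
                    "p_raw": res.p_raw,
                    "p_adjusted": res.p_adjusted,
                    "m": res.m,
                }
            )
        stats = pd.DataFrame(
            stats_rows,
            columns=["test", "method", "groups", "statistic", "p_raw", "p_adjusted", "m"],
        )
    except Exception:
        logger.exception("pipeline aborted in stage '%s'", stage)
        raise

    result = PipelineResult(
        matrix=matrix,
        partition=partition,
        eigengenes=eig,
        module_trait=_module_trait_long(mt),
        soft_threshold=fit_table,
        beta=beta,
        mpn_dag=mpn_dag,
        mpn_strength=strength.to_frame(),
        prioritization=ranking,
        top_module=top_module,
        gene_network=gene_net,
        epc=epc,
        hubs=hubs,
        hub_subnetwork=subnet,
        stats=stats,
    )
    result.manifest = _build_manifest(config, input_digests, result)
    if config.outdir:
        _write_outputs(Path(config.outdir), config, result)
    return result


def _build_manifest(config: PipelineConfig, input_digests: dict, result: PipelineResult) -> dict:
    from . import __version__

    return {
        "package_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {
            "mpn": stage_seed(config.seed, 1),
            "gene_network": stage_seed(config.seed, 2),
            "epc": stage_seed(config.seed, 3),
        },
        "input_digests": input_digests,
        "beta": result.beta,
        "n_modules": len(result.partition.module_labels),
        "module_sizes": {
            str(k): v for k, v in sorted(result.partition.sizes.items()) if k != 0
        },
        "top_module": result.top_module,
        "hubs": list(result.hubs),
        "output_digests": {},
    }


def _write_outputs(outdir: Path, config: PipelineConfig, result: PipelineResult) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    mpn_io.write_partition(result.partition.labels, outdir / "module_assignment.tsv")
    mpn_io.write_table(result.eigengenes.eigengenes, outdir / "eigengenes.tsv")
    result.module_trait.to_csv(outdir / "module_trait.tsv", sep="\t", index=False,
                               float_format="%.10g")
    if result.soft_threshold is not None:
        result.soft_threshold.to_csv(outdir / "soft_threshold.tsv", sep="\t",
                                     index=False, float_format="%.10g")
    mpn_io.write_network(result.mpn_dag, outdir / "mpn_network.tsv",
                         outdir / "mpn_network.graphml")
    result.mpn_strength.to_csv(outdir / "mpn_arc_strength.tsv", sep="\t",
                               index=False, float_format="%.10g")
    result.prioritization.to_csv(outdir / "prioritization.tsv", sep="\t",
                                 index=False, float_format="%.10g")
    mpn_io.write_network(result.gene_network, outdir / "gene_network.tsv",
                         outdir / "gene_network.graphml")
    epc_table = pd.DataFrame(
        {
            "epc": result.epc.scores,
            "degree": [
                result.gene_network.degree(g) if g in result.gene_network else 0
                for g in result.epc.scores.index
            ],
        }
    )
    epc_table["rank"] = (
        epc_table["epc"].rank(ascending=False, method="first").astype(int)
    )
    epc_table.index.name = "gene_id"
    mpn_io.write_table(epc_table, outdir / "epc_scores.tsv")
    nx.write_graphml(result.hub_subnetwork, outdir / "hub_subnetwork.graphml")
    result.stats.to_csv(outdir / "stats.tsv", sep="\t", index=False,
                        float_format="%.10g")
    digests = {
        path.name: _sha256(path)
        for path in sorted(outdir.iterdir())
        if path.name not in ("manifest.json", "run.log")
    }
    result.manifest["output_digests"] = digests
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                     sort_keys=True) + "\n")
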