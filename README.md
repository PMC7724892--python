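# mpn — module-to-phenotype networks for cognitive-reserve transcriptomics

Some people accumulate substantial Alzheimer's pathology — neurofibrillary
tangles, high Braak stage — yet keep near-normal cognition. That capacity
is called *cognitive reserve* (operationalized here as MMSE > 26 despite
Braak ≥ 3). `mpn` is a pipeline for asking which transcriptional programs
in post-mortem brain tissue sit *directly* behind that phenotype, rather
than merely correlating with it:

1. **Co-expression modules.** Genes are clustered into modules from a
   weighted co-expression network: Pearson similarity, soft-threshold
   power adjacency `a_ij = |cor_ij|^β` (β chosen by scale-free topology
   fit, R² ≥ 0.9), topological overlap
   `TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, and average-linkage
   tree cutting. Each module is summarized by its eigengene (first
   principal component), correlated with phenotypes under age/sex/PMI
   adjustment with Bonferroni correction.
2. **Module-phenotype network.** Eigengenes plus reserve, MMSE, Braak
   stage, and tangle counts enter a Gaussian Bayesian network learned by
   score-based hill climbing (Gaussian BIC) with bootstrap model
   averaging over 200 random restarts. Modules are prioritized by the
   phenotype content of their Markov blankets — a module whose blanket
   contains reserve and cognition depends on them *conditional on
   everything else*, which separates direct from merely correlated
   modules.
3. **Hub genes.** Within the prioritized module, a gene-level Bayesian
   network is learned the same way and genes are ranked by edge
   percolated component (EPC) centrality: keep each network edge with
   probability p = 0.5 and score a gene by the expected number of other
   genes still reachable from it. Top-6 genes and their neighbor
   subnetwork are exported.
4. **Validation statistics.** Welch t / ANOVA group contrasts with
   declared Bonferroni family sizes, a quartile contrast of longitudinal
   MMSE decline between high- and low-expression subjects, and projection
   of module eigengenes into external cohorts.

Because the cohorts this kind of study uses are access-restricted, the
package ships a first-class synthetic-cohort generator with planted
co-expression modules and module-driven phenotypes, so every stage is
testable against known ground truth. See `docs/methods.md` for the
generative model, all defaults, and known limitations.

## Worked example

```python
from mpn import SyntheticConfig, generate_dataset, PipelineConfig, run_pipeline

matrix, phenotypes, truth = generate_dataset(
    SyntheticConfig(n_samples=100, seed=2)
)
config = PipelineConfig(keep_fraction=1.0, beta=6, seed=2, n_restarts=100)
result = run_pipeline(config, matrix=matrix, phenotypes=phenotypes)

print("modules:", len(result.partition.module_labels))
print("top-ranked module:", result.top_module,
      "(planted:", f"M{truth.causal_module})")
print("hubs:", result.hubs)
print("planted hub:", truth.hub_gene)
mt = result.module_trait
row = mt[(mt.module == result.top_module) & (mt.trait == "mmse")].iloc[0]
print(f"cor(top module, MMSE) = {row.cor:.2f}, adjusted p = {row.p_adjusted:.1e}")
```

Output:

```
modules: 11
top-ranked module: M11 (planted: M11)
hubs: ['G2991', 'G2955', 'G2980', 'G2971', 'G2962', 'G2989']
planted hub: G2955
cor(top module, MMSE) = 0.63, adjusted p = 1.8e-10
```

All eleven planted modules are recovered; the module planted to drive
cognition is ranked first by the Markov-blanket rule, its eigengene
correlates 0.63 with MMSE after covariate adjustment, and the planted hub
gene (G2955) is among the six EPC hubs of its gene network. (The
top-ranking step is a stochastic inference; see the last section for how
often it succeeds across cohorts.)

The same pipeline runs from the shell on TSV inputs:

```bash
mpn simulate --seed 7 --n-samples 100 \
    --out-expression expr.tsv --out-phenotypes pheno.tsv
mpn run-all --expression expr.tsv --phenotypes pheno.tsv \
    --outdir out/ --seed 7 --keep-fraction 1.0
```

which writes module assignments, eigengenes, module–trait statistics, the
module- and gene-level networks (TSV + GraphML), EPC scores, the hub
subnetwork, group statistics, and a JSON manifest whose digests make the
run byte-for-byte reproducible.

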