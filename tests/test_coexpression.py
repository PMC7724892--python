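import numpy as np
import pandas as pd
import pytest

from mpn.coexpression import (
    adjacency,
    cluster_modules,
    connectivity,
    gene_significance_and_membership,
    module_eigengenes,
    module_trait_correlation,
    pearson_similarity,
    pick_soft_threshold,
    scale_free_fit,
    tom,
)
from mpn.containers import ModulePartition
from mpn.preprocess import zscore_normalize

from conftest import make_matrix


class TestPearsonSimilarity:
    def test_identity_and_antisymmetry(self, rng):
        x = rng.normal(size=6)
        m = make_matrix(np.vstack([x, -x, rng.normal(size=6)]))
        sim = pearson_similarity(m)
        assert sim.iloc[0, 0] == pytest.approx(1.0)
        assert sim.iloc[0, 1] == pytest.approx(-1.0)
        np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T)

    def test_matches_pairwise_brute_force(self, rng):
        m = make_matrix(rng.normal(size=(3, 6)))
        sim = pearson_similarity(m)
        x = m.values.to_numpy()
        for i in range(3):
            for j in range(3):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                want = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert sim.iloc[i, j] == pytest.approx(want, abs=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_similarity(make_matrix([[1, 1, 1], [1, 2, 3]]))


class TestAdjacency:
    def test_power_values(self):
        sim = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        adj = adjacency(sim, 6)
        assert adj.loc["a", "b"] == pytest.approx(0.5**6)
        assert adjacency(sim, 1).loc["a", "b"] == pytest.approx(0.5)
        neg = sim.copy()
        neg.loc["a", "b"] = neg.loc["b", "a"] = -1.0
        assert adjacency(neg, 6).loc["a", "b"] == pytest.approx(1.0)

    def test_beta_below_one_rejected(self):
        sim = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            adjacency(sim, 0)


class TestTOM:
    def test_three_node_hand_fixture(self):
        # all pairwise a = 0.5: k = 1 each, l_ij = 0.25,
        # TOM_ij = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        a = pd.DataFrame(0.5, index=list("abc"), columns=list("abc"))
        np.fill_diagonal(a.values, 1.0)
        t = tom(a)
        for i, j in (("a", "b"), ("a", "c"), ("b", "c")):
            assert t.loc[i, j] == pytest.approx(0.5, abs=1e-12)
        assert (np.diag(t.to_numpy()) == 1.0).all()

    def test_disconnected_pair_is_zero(self):
        a = pd.DataFrame(0.0, index=list("abcd"), columns=list("abcd"))
        np.fill_diagonal(a.values, 1.0)
        a.loc["a", "b"] = a.loc["b", "a"] = 0.9
        a.loc["c", "d"] = a.loc["d", "c"] = 0.9
        t = tom(a)
        assert t.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)

    def test_bounds_and_symmetry(self, rng):
        raw = rng.uniform(0, 1, size=(15, 15))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 1.0)
        t = tom(pd.DataFrame(a, index=range(15), columns=range(15))).to_numpy()
        assert t.min() >= 0 and t.max() <= 1
        np.testing.assert_allclose(t, t.T)

    def test_monotone_in_adjacency(self):
        base = pd.DataFrame(0.3, index=list("abcd"), columns=list("abcd"))
        np.fill_diagonal(base.values, 1.0)
        bumped = base.copy()
        bumped.loc["a", "b"] = bumped.loc["b", "a"] = 0.6
        t0 = tom(base).loc["a", "b"]
        t1 = tom(bumped).loc["a", "b"]
        assert t1 > t0


class TestSoftThreshold:
    def test_exact_power_law_degrees_fit_well(self):
        # frequencies proportional to k^-2 give a log-log line by construction
        ks = np.linspace(1, 40, 40)
        counts = np.round(4000 * ks**-2.0).astype(int)
        k = np.repeat(ks, counts)
        r2, slope = scale_free_fit(k, n_bins=10)
        assert r2 >= 0.9
        assert slope < 0

    def test_positive_slope_penalized(self):
        k = np.repeat(np.arange(1, 21), np.arange(1, 21))  # increasing freq
        r2, slope = scale_free_fit(k, n_bins=8)
        assert slope > 0
        assert r2 <= 0

    def test_fallback_flags_warning(self, rng):
        # pure-noise correlations never reach a 0.999 fit
        sim = pearson_similarity(make_matrix(rng.normal(size=(40, 60))))
        res = pick_soft_threshold(sim, candidate_powers=(1, 2), r2_cutoff=0.999)
        assert res.warning
        assert res.beta in (1, 2)
        assert len(res.fit_table) == 2

    def test_selects_smallest_passing_power(self, default_cohort):
        matrix, _, _ = default_cohort
        sub = zscore_normalize(make_matrix(
            matrix.values.to_numpy()[:800], normalized=False))
        sim = pearson_similarity(sub)
        res = pick_soft_threshold(sim, candidate_powers=tuple(range(1, 13)))
        table = res.fit_table.set_index("power")["r_squared"]
        if not res.warning:
            assert table.loc[res.beta] >= 0.9
            assert (table.loc[: res.beta - 1] < 0.9).all()

    def test_connectivity_excludes_diagonal(self):
        a = pd.DataFrame(0.5, index=list("ab"), columns=list("ab"))
        np.fill_diagonal(a.values, 1.0)
        assert connectivity(a).tolist() == [0.5, 0.5]


class TestClusterModules:
    def test_two_planted_blocks(self, rng):
        n = 100
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        block1 = 0.95 * f1 + 0.3 * rng.normal(size=(40, n))
        block2 = 0.95 * f2 + 0.3 * rng.normal(size=(40, n))
        m = zscore_normalize(make_matrix(np.vstack([block1, block2])))
        t = tom(adjacency(pearson_similarity(m), 6))
        part = cluster_modules(t, min_module_size=10, cut_height=0.998)
        assert len(part.module_labels) == 2
        lab = part.labels.to_numpy()
        assert len(set(lab[:40])) == 1 and len(set(lab[40:])) == 1
        assert lab[0] != lab[40]

    def test_uncorrelated_genes_all_grey(self, rng):
        m = zscore_normalize(make_matrix(rng.normal(size=(60, 50))))
        t = tom(adjacency(pearson_similarity(m), 6))
        part = cluster_modules(t, min_module_size=30, cut_height=0.998)
        assert part.module_labels == []
        assert (part.labels == 0).all()

    def test_labels_ordered_by_size(self, default_cohort):
        matrix, _, _ = default_cohort
        z = zscore_normalize(make_matrix(matrix.values.to_numpy()))
        t = tom(adjacency(pearson_similarity(z), 6))
        part = cluster_modules(t)
        sizes = [part.sizes[lab] for lab in part.module_labels]
        assert sizes == sorted(sizes, reverse=True)

    def test_planted_module_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        from mpn.synthetic import SyntheticConfig, generate_dataset

        good = 0
        for seed in range(5):
            matrix, _, truth = generate_dataset(SyntheticConfig(n_samples=100, seed=seed))
            z = zscore_normalize(matrix)
            t = tom(adjacency(pearson_similarity(z), 6))
            part = cluster_modules(t)
            if adjusted_rand_score(truth.module_assignment, part.labels) >= 0.8:
                good += 1
        assert good >= 4


class TestModuleEigengenes:
    def test_identical_profiles_module(self, rng):
        x = rng.normal(size=12)
        m = make_matrix(np.vstack([x, x, x]), normalized=False)
        part = ModulePartition(pd.Series([1, 1, 1], index=m.gene_ids))
        eig = module_eigengenes(m, part)
        me = eig.eigengenes.loc["M1"]
        for row in m.values.to_numpy():
            assert abs(np.corrcoef(me, row)[0, 1]) == pytest.approx(1.0, abs=1e-8)
        assert eig.variance_explained["M1"] == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention(self, small_cohort):
        matrix, _, _ = small_cohort
        z = zscore_normalize(matrix)
        part = ModulePartition(
            pd.Series(
                np.repeat([1, 2], 200), index=matrix.gene_ids
            )
        )
        eig = module_eigengenes(z, part)
        for label in (1, 2):
            genes = part.genes_in(label)
            mean_profile = z.values.loc[genes].mean(axis=0)
            r = np.corrcoef(eig.eigengenes.loc[f"M{label}"], mean_profile)[0, 1]
            assert r >= 0

    def test_variance_explained_matches_full_svd(self, rng):
        x = rng.normal(size=(20, 15))
        m = zscore_normalize(make_matrix(x))
        part = ModulePartition(pd.Series(1, index=m.gene_ids))
        eig = module_eigengenes(m, part)
        sub = m.values.to_numpy()
        sub = (sub - sub.mean(1, keepdims=True)) / sub.std(1, ddof=1, keepdims=True)
        s = np.linalg.svd(sub, compute_uv=False)
        assert eig.variance_explained["M1"] == pytest.approx(
            s[0] ** 2 / (s**2).sum(), abs=1e-12
        )

    def test_rank_one_module_recovers_factor(self, rng):
        n = 40
        f = rng.normal(size=n)
        x = 0.8 * f + 0.2 * rng.normal(size=(25, n))
        m = zscore_normalize(make_matrix(x))
        part = ModulePartition(pd.Series(1, index=m.gene_ids))
        eig = module_eigengenes(m, part)
        assert abs(np.corrcoef(eig.eigengenes.loc["M1"], f)[0, 1]) >= 0.99


class TestModuleTraitCorrelation:
    def test_trait_equal_to_eigengene(self, rng):
        eig = pd.DataFrame(
            rng.normal(size=(2, 30)), index=["M1", "M2"],
            columns=[f"s{i}" for i in range(30)],
        )
        traits = pd.DataFrame({"t": eig.loc["M1"]})
        res = module_trait_correlation(eig, traits)
        assert res.correlation.loc["M1", "t"] == pytest.approx(1.0)
        assert res.p_raw.loc["M1", "t"] < 1e-20
        assert res.n_tests == 2

    def test_collinear_trait_covariate_rejected(self, rng):
        eig = pd.DataFrame(
            rng.normal(size=(1, 20)), index=["M1"],
            columns=[f"s{i}" for i in range(20)],
        )
        c = rng.normal(size=20)
        traits = pd.DataFrame({"t": c, "cov": c}, index=eig.columns)
        with pytest.raises(ValueError, match="collinear"):
            module_trait_correlation(eig, traits, covariates=["cov"])

    def test_partial_correlation_against_pingouin(self, default_cohort):
        import pingouin as pg

        matrix, pheno, truth = default_cohort
        eig = pd.DataFrame(
            truth.factor_values.T.to_numpy(),
            index=[f"M{i+1}" for i in range(11)],
            columns=matrix.sample_ids,
        )
        from mpn.preprocess import encode_traits

        traits = encode_traits(pheno)[["mmse", "age", "sex", "pmi"]]
        res = module_trait_correlation(eig, traits, covariates=["age", "sex", "pmi"])
        df = pd.DataFrame(
            {
                "me": eig.loc[f"M{truth.causal_module}"],
                "mmse": traits["mmse"],
                "age": traits["age"],
                "sex": traits["sex"],
                "pmi": traits["pmi"],
            }
        )
        want = pg.partial_corr(df, x="me", y="mmse", covar=["age", "sex", "pmi"])
        assert res.correlation.loc[f"M{truth.causal_module}", "mmse"] == pytest.approx(
            float(want["r"].iloc[0]), abs=1e-10
        )
        assert res.p_raw.loc[f"M{truth.causal_module}", "mmse"] == pytest.approx(
            float(want["p_val"].iloc[0]), rel=1e-6
        )

    def test_bonferroni_spans_grid(self, rng):
        eig = pd.DataFrame(
            rng.normal(size=(3, 25)), index=["M1", "M2", "M3"],
            columns=[f"s{i}" for i in range(25)],
        )
        traits = pd.DataFrame(
            rng.normal(size=(25, 2)), index=eig.columns, columns=["a", "b"]
        )
        res = module_trait_correlation(eig, traits)
        assert res.n_tests == 6
        np.testing.assert_allclose(
            res.p_adjusted.to_numpy(),
            np.minimum(1.0, res.p_raw.to_numpy() * 6),
        )


class TestGeneSignificance:
    def test_gs_one_for_trait_gene_and_mm_zero_orthogonal(self, rng):
        n = 24
        trait = rng.normal(size=n)
        trait -= trait.mean()
        ortho = rng.normal(size=n)
        ortho -= ortho.mean()
        ortho -= ortho @ trait / (trait @ trait) * trait
        m = make_matrix(np.vstack([trait, ortho]))
        eig = pd.DataFrame([trait], index=["M1"], columns=m.sample_ids)
        res = gene_significance_and_membership(
            m, eig, pd.Series(trait, index=m.sample_ids)
        )
        assert res.gene_significance.loc["g0"] == pytest.approx(1.0)
        assert res.module_membership.loc["g1", "M1"] == pytest.approx(0.0, abs=1e-10)

    def test_causal_module_mm_gs_exceeds_noise(self):
        from mpn.synthetic import SyntheticConfig, generate_dataset

        wins = 0
        for seed in range(5):
            matrix, pheno, truth = generate_dataset(
                SyntheticConfig(n_samples=100, n_genes=600, seed=seed)
            )
            z = zscore_normalize(matrix)
            part = ModulePartition(truth.module_assignment.copy())
            eig = module_eigengenes(z, part)
            res = gene_significance_and_membership(
                z, eig.eigengenes,
                pheno["mmse"].astype(float), partition=part,
            )
            table = res.module_mm_gs_cor.set_index("module")["cor_mm_gs"]
            causal = table[f"M{truth.causal_module}"]
            noise = table.drop(f"M{truth.causal_module}")
            if causal > 0 and causal > noise.median():
                wins += 1
        assert wins >= 4


def test_gene_permutation_invariance(rng):
    x = rng.normal(size=(30, 20))
    m = zscore_normalize(make_matrix(x))
    perm = rng.permutation(30)
    mp = zscore_normalize(make_matrix(x[perm], gene_ids=[f"g{i}" for i in perm]))
    t = tom(adjacency(pearson_similarity(m), 6))
    tp = tom(adjacency(pearson_similarity(mp), 6))
    np.testing.assert_allclose(
        t.loc[mp.gene_ids, mp.gene_ids].to_numpy(), tp.to_numpy(), atol=1e-12
    )
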