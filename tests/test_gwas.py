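"""Association engine: encoding, PCA, scan statistics, permutation
thresholds, significance calls and gene mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pavscape.core import GeneAnnotation, GeneModel, GenotypeMatrix, MISSING
from pavscape.gwas import (
    PermutationSpec,
    association_scan,
    call_significant,
    compute_pcs,
    empirical_quantile,
    encode_genotypes,
    map_to_genes,
    permutation_threshold,
)
from pavscape.simulate import (
    SimulationConfig,
    TraitSpec,
    simulate_pav_truth,
    simulate_phenotypes,
)


def _matrix(geno):
    geno = np.asarray(geno, dtype=np.int8)
    n_s, n_l = geno.shape
    loci = pd.DataFrame({
        "locus_id": [f"locus{j + 1:05d}" for j in range(n_l)],
        "chrom": "chr1", "start": np.arange(1, n_l + 1) * 1000,
        "end": np.arange(1, n_l + 1) * 1000 + 60, "svtype": "DEL",
        "size": 60, "callers": "c", "n_members": 1})
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n_s)], loci=loci,
                          genotypes=geno)


class TestEncoding:
    def test_mean_imputation(self):
        m = _matrix([[1], [0], [MISSING], [1]])
        X, usable = encode_genotypes(m)
        assert X[:, 0] == pytest.approx([1, 0, 2 / 3, 1])
        assert usable[0]

    def test_monomorphic_flagged(self):
        X, usable = encode_genotypes(_matrix([[0, 1], [0, 0], [0, 1]]))
        assert not usable[0] and usable[1]

    def test_no_missing_is_plain_binary(self):
        geno = [[1, 0], [0, 1], [1, 1]]
        X, _ = encode_genotypes(_matrix(geno))
        assert np.array_equal(X, np.array(geno, dtype=float))


class TestPca:
    def test_variance_ratios_sum_to_one(self):
        rng = np.random.default_rng(0)
        X = rng.random((20, 50))
        basis = compute_pcs(X, k=3)
        assert basis.variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_concentrates_variance(self):
        u = np.arange(10, dtype=float)[:, None]
        v = np.ones((1, 5))
        basis = compute_pcs(u @ v, k=2)
        assert basis.variance_ratio[0] == pytest.approx(1.0)

    def test_pc1_separates_subpopulations(self):
        """Two subpopulations with independent allele frequencies: PC1 is
        nearly binary in the subpopulation label (|r| > 0.9)."""
        cfg = SimulationConfig(seed=41, n_samples=50, n_true_pavs=200,
                               subpop_fraction=0.5, n_genes=0)
        truth = simulate_pav_truth(cfg)
        basis = compute_pcs(truth.genotypes.astype(float), k=3)
        labels = truth.subpopulation_labels.astype(float)
        r = np.corrcoef(basis.scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.random((15, 8))
        a = compute_pcs(X, k=3)
        b = compute_pcs(X.copy(), k=3)
        assert np.allclose(a.scores, b.scores)
        for j in range(3):
            assert a.loadings[j, np.argmax(np.abs(a.loadings[j]))] > 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="sample count"):
            compute_pcs(np.zeros((4, 10)), k=4)


class TestAssociationScan:
    def test_binary_locus_closed_form(self):
        """Regression on a balanced binary predictor equals the pooled
        two-sample t-test: effect 10, t = 10/sqrt(2/3), df 4."""
        g = np.array([[0], [0], [0], [1], [1], [1]], dtype=float)
        y = np.array([1, 2, 3, 11, 12, 13], dtype=float)
        res = association_scan(g, y)
        assert res.loc[0, "effect"] == pytest.approx(10.0)
        assert res.loc[0, "t"] == pytest.approx(10 / np.sqrt(2 / 3), rel=1e-9)
        t_ref = stats.ttest_ind(y[3:], y[:3], equal_var=True)
        assert res.loc[0, "p"] == pytest.approx(t_ref.pvalue, abs=1e-12)
        assert res.loc[0, "p"] == pytest.approx(2.6e-4, rel=0.02)

    def test_matches_pooled_t_test_everywhere(self):
        rng = np.random.default_rng(2)
        g = (rng.random((40, 30)) < 0.4).astype(float)
        y = rng.normal(size=40)
        res = association_scan(g, y)
        for j in range(30):
            col = g[:, j]
            if col.std() == 0:
                continue
            ref = stats.ttest_ind(y[col == 1], y[col == 0], equal_var=True)
            assert res.loc[j, "p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_null_p_values_uniform(self):
        """Independent phenotype: the per-scan KS statistic against U(0,1)
        stays below the 1% critical value in >=95 of 100 seeds."""
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = (rng.random((150, 400)) < rng.uniform(0.1, 0.9, 400)).astype(float)
            y = rng.normal(size=150)
            res = association_scan(g, y)
            crit = 1.628 / np.sqrt(len(res))  # 1% asymptotic KS critical value
            stat = stats.kstest(res["p"], "uniform").statistic
            ok += stat < crit
        assert ok >= 95

    def test_covariate_absorbs_its_own_signal(self):
        c = np.tile([1.0, -1.0], 4)
        g = np.array([1, 1, 0, 0, 1, 1, 0, 0], dtype=float)[:, None]
        y = c.copy()
        res = association_scan(g, y, covariates=c)
        assert res.loc[0, "effect"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[0, "p"] > 0.5

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            association_scan(np.ones((5, 1)), np.ones(5))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            association_scan(np.ones((3, 1)), np.array([1.0, 2.0, 3.0]),
                             covariates=np.eye(3, 2))

    def test_missing_phenotypes_dropped(self):
        g = np.array([[0], [0], [1], [1], [0]], dtype=float)
        y = np.array([1.0, 2.0, 5.0, 6.0, np.nan])
        res = association_scan(g, y)
        ref = association_scan(g[:4], y[:4])
        assert res.loc[0, "p"] == pytest.approx(ref.loc[0, "p"])


class TestPermutationThreshold:
    def test_quantile_conventions(self):
        assert empirical_quantile(np.full(100, 3.3), 0.95) == 3.3
        vals = np.arange(1, 1001, dtype=float)  # threshold = 950th order stat
        assert empirical_quantile(vals, 0.95) == 950.0

    def test_threshold_weakly_increases_as_alpha_drops(self):
        rng = np.random.default_rng(5)
        g = (rng.random((60, 200)) < 0.4).astype(float)
        y = rng.normal(size=60)
        thr = {a: permutation_threshold(
            g, y, spec=PermutationSpec(n_permutations=100, alpha=a, seed=9))
            for a in (0.20, 0.05, 0.01)}
        assert thr[0.01] >= thr[0.05] >= thr[0.20]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        g = (rng.random((40, 100)) < 0.4).astype(float)
        y = rng.normal(size=40)
        spec = PermutationSpec(n_permutations=50, alpha=0.1, seed=3)
        assert permutation_threshold(g, y, spec=spec) == \
            permutation_threshold(g, y, spec=spec)

    def test_too_few_permutations_warn(self):
        rng = np.random.default_rng(7)
        g = (rng.random((30, 20)) < 0.4).astype(float)
        y = rng.normal(size=30)
        with pytest.warns(UserWarning, match="permutations"):
            permutation_threshold(
                g, y, spec=PermutationSpec(n_permutations=10, alpha=0.05))

    def test_pc_covariates_deflate_structure_confounding(self):
        """With a subpopulation phenotype shift and no causal loci, the
        median -log10(p) over loci is smaller with 3 PC covariates than
        without, in each of 20 seeds' aggregate."""
        diffs = []
        for seed in range(20):
            cfg = SimulationConfig(seed=500 + seed, n_samples=100,
                                   n_true_pavs=300, causal_pavs=(),
                                   subpop_phenotype_shift=1.0,
                                   traits=(TraitSpec("y"),), n_genes=0)
            truth = simulate_pav_truth(cfg)
            y = simulate_phenotypes(truth, cfg)["y"].to_numpy()
            X = truth.genotypes.astype(float)
            basis = compute_pcs(X, k=3)
            with_pcs = association_scan(X, y, basis.scores)["minus_log10_p"]
            without = association_scan(X, y)["minus_log10_p"]
            diffs.append(np.median(without) - np.median(with_pcs))
        assert np.median(diffs) > 0
        assert np.mean(np.array(diffs) > 0) >= 0.8

    def test_planted_effect_recovered_within_20pct(self):
        """Median estimated effect of the causal locus across 50 seeds is
        within 20% of the planted effect (n=300, 25% variance explained)."""
        rel = []
        for seed in range(50):
            cfg = SimulationConfig(seed=700 + seed, n_samples=300,
                                   n_true_pavs=200,
                                   causal_pavs=(("random", 0.25),),
                                   traits=(TraitSpec("y"),), n_genes=0)
            truth = simulate_pav_truth(cfg)
            y = simulate_phenotypes(truth, cfg)["y"].to_numpy()
            X = truth.genotypes.astype(float)
            basis = compute_pcs(X, k=3)
            res = association_scan(X, y, basis.scores)
            idx, effect = next(iter(truth.causal_effects["y"].items()))
            rel.append(res.loc[idx, "effect"] / effect)
        assert abs(np.median(rel) - 1.0) < 0.2


class TestSignificanceAndGenes:
    def test_unreachable_threshold_empty(self):
        res = pd.DataFrame({"locus_id": ["a"], "effect": [1.0], "se": [1.0],
                            "t": [1.0], "p": [0.3], "minus_log10_p": [0.52]})
        assert call_significant(res, 10.0).empty

    def test_tie_at_threshold_included(self):
        res = pd.DataFrame({"locus_id": ["a", "b"], "effect": [1, 1],
                            "se": [1, 1], "t": [1, 1], "p": [0.01, 0.3],
                            "minus_log10_p": [2.0, 0.52]})
        sig = call_significant(res, 2.0)
        assert list(sig["locus_id"]) == ["a"]

    def test_gene_mapping_geometry(self):
        """A 55 bp deletion 615 bp upstream and a deletion in the first
        intron both map to the gene; a locus 10 kb away maps to nothing."""
        gene = GeneModel(gene_id="g1", chrom="chr1", start=50_000, end=60_000,
                         strand="+", exons=[(50_000, 52_000), (54_000, 60_000)],
                         cds=[(50_000, 52_000), (54_000, 60_000)], utrs=[])
        ann = GeneAnnotation(genes=[gene])
        loci = pd.DataFrame({
            "locus_id": ["up615", "intron1", "far"],
            "chrom": "chr1",
            "start": [50_000 - 615 - 55, 52_500, 75_000],
            "end": [50_000 - 615, 52_555, 75_100],
            "svtype": "DEL", "size": [55, 55, 100]})
        sig = pd.DataFrame({"locus_id": ["up615", "intron1", "far"]})
        table = map_to_genes(sig, loci, ann, flank_bp=3000)
        assert set(table[table.locus_id == "up615"]["gene_id"]) == {"g1"}
        assert set(table[table.locus_id == "intron1"]["gene_id"]) == {"g1"}
        assert table[table.locus_id == "far"].empty
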