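"""Tests for cofitness, QC metrics, polarity and expression comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poolfit as pf
from poolfit import compendium as cp
from poolfit import gene_scoring as gs
from poolfit.util import ParameterError


@pytest.fixture(scope="module")
def gene_fit(fitness_matrix):
    return pf.gene_fitness(fitness_matrix)


class TestCofitnessPvalue:
    def test_zero_correlation_is_uninformative(self):
        assert cp.cofitness_pvalue(0.0, 50) == pytest.approx(1.0)

    def test_closed_form_example(self):
        # r=0.5, n=10: t = 0.5*sqrt(8)/sqrt(0.75) = 1.633, df=8
        assert cp.cofitness_pvalue(0.5, 10) == pytest.approx(0.141, abs=0.002)

    def test_perfect_correlation_maps_to_zero(self):
        assert cp.cofitness_pvalue(1.0, 10) == 0.0
        assert cp.cofitness_pvalue(-1.0, 10) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ParameterError):
            cp.cofitness_pvalue(0.5, 2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0, 0.99), st.floats(0, 0.99), st.integers(5, 200))
    def test_monotone_decreasing_in_abs_r(self, r1, r2, n):
        p1, p2 = cp.cofitness_pvalue(r1, n), cp.cofitness_pvalue(r2, n)
        if abs(r1) < abs(r2):
            assert p1 >= p2


class TestCofitness:
    def test_perfect_and_anti_correlated_pairs(self):
        x = np.linspace(-2, 2, 12)
        fit = pd.DataFrame([x, -x, x * 2], index=["gA", "gB", "gC"],
                           columns=[f"e{i}" for i in range(12)])
        cof = cp.cofitness(fit, min_experiments=10)
        cof = cof.set_index(["gene_a", "gene_b"])
        assert cof.loc[("gA", "gB"), "r"] == pytest.approx(-1.0)
        assert cof.loc[("gA", "gC"), "r"] == pytest.approx(1.0)

    def test_low_overlap_pairs_are_omitted(self):
        rng = np.random.default_rng(5)
        fit = pd.DataFrame(rng.normal(size=(3, 12)), index=["gA", "gB", "gC"],
                           columns=[f"e{i}" for i in range(12)])
        fit.loc["gB", fit.columns[:6]] = np.nan  # only 6 shared experiments
        cof = cp.cofitness(fit, min_experiments=10)
        pairs = set(zip(cof["gene_a"], cof["gene_b"]))
        assert ("gA", "gB") not in pairs and ("gA", "gC") in pairs

    def test_constant_gene_is_omitted(self):
        rng = np.random.default_rng(6)
        fit = pd.DataFrame(rng.normal(size=(2, 12)), index=["gA", "gB"],
                           columns=[f"e{i}" for i in range(12)])
        fit.loc["gB"] = 1.0
        cof = cp.cofitness(fit, min_experiments=10)
        assert len(cof) == 0

    def test_operon_mates_show_high_cofitness(self):
        g = pf.simulate_genome(150, seed=71)
        lib = pf.simulate_insertion_library(g, 350, 0.0, seed=72)
        pools = pf.assemble_pools(lib, seed=73)
        truth = pf.simulate_truth(g, 16, 6, sparsity=0.08, operon_share=1.0,
                                  effect_scale=2.5, seed=74)
        table = pf.simulate_intensities(pools, truth, probe_sd=0.3, seed=75)
        m = pf.compute_strain_fitness(table, pools.strains, g)
        fit = pf.gene_fitness(m)[truth.conditions]
        pairs = g.operon_pairs()
        rs = []
        affected = truth.matrix[truth.conditions].abs().sum(axis=1) > 0
        for _, row in pairs.iterrows():
            a, b = row["upstream"], row["downstream"]
            if a in fit.index and b in fit.index and affected.get(a, False):
                x, y = fit.loc[a].to_numpy(), fit.loc[b].to_numpy()
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() >= 10 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                    rs.append(np.corrcoef(x[ok], y[ok])[0, 1])
        assert np.median(rs) > 0.7


class TestExperimentQC:
    def test_identical_pool_values_give_unit_r_same(self):
        idx = pd.MultiIndex.from_tuples(
            [(f"s{i}", p) for i in range(5) for p in ("up", "dn")],
            names=["strain_id", "pool"])
        vals = pd.DataFrame({"e1": np.repeat(np.linspace(-2, 2, 5), 2)}, index=idx)
        prov = pd.DataFrame({"pool": idx.get_level_values("pool"),
                             "replicon": "chromosome", "plate": "P1",
                             "gene_id": "gX", "gene_fraction": 0.5}, index=idx)
        m = pf.StrainFitnessMatrix(values=vals, provenance=prov,
                                   experiments=pd.DataFrame())
        pairs = pd.DataFrame(columns=["upstream", "downstream"])
        qc = cp.experiment_qc(m, pairs, pd.DataFrame(index=pd.Index([])))
        assert qc.loc[0, "r_same"] == pytest.approx(1.0)

    def test_signal_experiments_have_high_r_same(self, fitness_matrix, dataset,
                                                 gene_fit):
        pairs = dataset["genome"].operon_pairs()
        qc = cp.experiment_qc(fitness_matrix, pairs, gene_fit)
        qc = qc.set_index("experiment_id")
        conds = dataset["truth"].conditions
        assert qc.loc[conds, "r_same"].median() > 0.5

    def test_noise_only_experiments_have_null_r_operon(self, genome):
        pairs = genome.operon_pairs()
        rng = np.random.default_rng(77)
        medians = []
        for _ in range(20):
            fit = pd.DataFrame(rng.normal(size=(len(genome.genes), 12)),
                               index=genome.gene_ids,
                               columns=[f"e{i}" for i in range(12)])
            rs = []
            for _, row in pairs.iterrows():
                x = fit.loc[row["upstream"]].to_numpy()
                y = fit.loc[row["downstream"]].to_numpy()
                rs.append(np.corrcoef(x, y)[0, 1])
            medians.append(np.median(rs))
        assert abs(np.median(medians)) < 0.05


class TestPolarity:
    def test_printed_scale_counts_are_highly_significant(self):
        assert cp.polarity_binomial_pvalue(3333, 2233) < 1e-15

    def test_balanced_counts_are_null(self):
        assert cp.polarity_binomial_pvalue(10, 10) == pytest.approx(1.0)

    def test_three_pair_toy_matrix_matches_hand_enumeration(self):
        pairs = pd.DataFrame({"upstream": ["a", "c", "e"],
                              "downstream": ["b", "d", "f"]})
        fit = pd.DataFrame({
            "e1": {"a": -3.0, "b": 0.0, "c": 0.0, "d": -3.0, "e": -3.0, "f": -3.0},
            "e2": {"a": -3.0, "b": 0.0, "c": -0.5, "d": 0.0, "e": 0.0, "f": 0.0},
        })
        res = cp.polarity_counts(fit, pairs)
        # by hand: up-only = (a,b)@e1, (a,b)@e2; down-only = (c,d)@e1
        assert (res.up_only, res.down_only) == (2, 1)

    def test_brute_force_equivalence_on_simulated_data(self, gene_fit, dataset):
        pairs = dataset["genome"].operon_pairs()
        res = cp.polarity_counts(gene_fit, pairs)
        up = down = 0
        for _, row in pairs.iterrows():
            for exp in gene_fit.columns:
                try:
                    fu = gene_fit.loc[row["upstream"], exp]
                    fd = gene_fit.loc[row["downstream"], exp]
                except KeyError:
                    continue
                if fu < -2 and fd > -1:
                    up += 1
                if fd < -2 and fu > -1:
                    down += 1
        assert (res.up_only, res.down_only) == (up, down)


class TestAuxotrophConcordance:
    def test_clear_auxotrophs(self):
        fit = pd.DataFrame({"minimal": [-3.0, -3.0], "rich": [0.0, 0.0]},
                           index=["gA", "gB"])
        res = cp.auxotroph_concordance(fit, ["gA", "gB"], "minimal", "rich")
        assert (res.fraction_minimal, res.fraction_rich) == (1.0, 0.0)

    def test_empty_prediction_set_is_rejected(self):
        fit = pd.DataFrame({"minimal": [0.0], "rich": [0.0]}, index=["gA"])
        with pytest.raises(ParameterError):
            cp.auxotroph_concordance(fit, [], "minimal", "rich")

    def test_missing_genes_are_reported(self):
        fit = pd.DataFrame({"minimal": [-3.0], "rich": [0.0]}, index=["gA"])
        res = cp.auxotroph_concordance(fit, ["gA", "gZ"], "minimal", "rich")
        assert res.missing == ["gZ"] and res.n_used == 1


class TestSignificanceBins:
    def test_flat_correlations_give_flat_medians(self):
        tests = pd.DataFrame({"chisq": np.linspace(1, 50, 40)},
                             index=[f"g{i}" for i in range(40)])
        corr = pd.Series(0.3, index=tests.index)
        out = cp.operon_cofitness_by_significance(tests, corr, n_bins=4)
        assert np.allclose(out["r_median"], 0.3)

    def test_too_many_bins_rejected(self):
        tests = pd.DataFrame({"chisq": [1.0, 2.0]}, index=["g0", "g1"])
        corr = pd.Series(0.3, index=tests.index)
        with pytest.raises(ParameterError):
            cp.operon_cofitness_by_significance(tests, corr, n_bins=10)

    def test_signal_gives_rising_trend(self, scores, gene_fit, dataset):
        pairs = dataset["genome"].operon_pairs()
        conds = dataset["truth"].conditions
        corr = cp.operon_neighbor_correlation(gene_fit[conds], pairs)
        out = cp.operon_cofitness_by_significance(scores.phenotypes, corr, n_bins=5)
        from scipy.stats import spearmanr
        rho = spearmanr(out["bin"], out["r_median"]).statistic
        assert rho > 0


class TestFitnessExpression:
    def test_exact_anticorrelation(self):
        genes = [f"g{i}" for i in range(12)]
        fa = pd.Series(np.linspace(-3, 1, 12), index=genes)
        fb = pd.Series(0.0, index=genes)
        expr = -(fa - fb)
        res = cp.fitness_expression_comparison(fa, fb, expr)
        assert res.correlation == pytest.approx(-1.0)

    def test_quadrant_assignment(self):
        genes = ["gA"] + [f"g{i}" for i in range(11)]
        fa = pd.Series([-3.0] + [1.0] * 11, index=genes)
        fb = pd.Series(0.0, index=genes)
        expr = pd.Series([2.0] + [-1.0] * 11, index=genes)
        res = cp.fitness_expression_comparison(fa, fb, expr)
        assert "gA" in res.quadrants["up_regulated_more_important"]

    def test_independent_matrices_are_uncorrelated(self):
        rng = np.random.default_rng(81)
        genes = [f"g{i}" for i in range(300)]
        fa = pd.Series(rng.normal(size=300), index=genes)
        fb = pd.Series(rng.normal(size=300), index=genes)
        expr = pd.Series(rng.normal(size=300), index=genes)
        res = cp.fitness_expression_comparison(fa, fb, expr)
        assert abs(res.correlation) < 0.15

    def test_no_shared_genes_is_rejected(self):
        fa = pd.Series([1.0], index=["gA"])
        fb = pd.Series([1.0], index=["gA"])
        expr = pd.Series([1.0], index=["gZ"])
        with pytest.raises(ParameterError):
            cp.fitness_expression_comparison(fa, fb, expr)

    def test_excluded_genes_are_reported(self):
        genes = [f"g{i}" for i in range(12)]
        fa = pd.Series(np.linspace(-3, 1, 12), index=genes)
        fb = pd.Series(0.0, index=genes)
        expr = -(fa - fb)
        flags = pd.Series(False, index=genes)
        flags["g0"] = True  # e.g. sick on rich media
        res = cp.fitness_expression_comparison(fa, fb, expr, exclude=flags)
        assert res.excluded == ["g0"]
        assert "g0" not in res.relative_fitness.index
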