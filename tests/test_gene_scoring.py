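"""Tests for gene fitness, the t-like statistic and the empirical null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import poolfit as pf
from poolfit import gene_scoring as gs
from poolfit.util import CalibrationError, ParameterError

from conftest import make_strain_matrix


class TestGoodInsertions:
    @pytest.mark.parametrize("frac, expected", [
        (0.5, True), (0.9, False), (0.05, True), (0.80, True),
        (0.049, False), (0.801, False), (np.nan, False),
    ])
    def test_window_rule(self, frac, expected):
        assert bool(pf.good_insertions([frac])[0]) is expected


class TestGeneFitness:
    def test_good_insertions_exclude_edge_strains(self):
        vals = {("s1", "up"): {"e1": -2.0}, ("s2", "up"): {"e1": -1.0},
                ("s3", "up"): {"e1": 0.0}}
        prov = {("s1", "up"): ("chromosome", "P1", "gA", 0.5),
                ("s2", "up"): ("chromosome", "P1", "gA", 0.3),
                ("s3", "up"): ("chromosome", "P1", "gA", 0.95)}
        m = make_strain_matrix(vals, prov)
        fit = pf.gene_fitness(m)
        assert fit.loc["gA", "e1"] == pytest.approx(-1.5)

    def test_edge_only_gene_falls_back_to_all_insertions(self):
        vals = {("s1", "up"): {"e1": -3.0}}
        prov = {("s1", "up"): ("chromosome", "P1", "gA", 0.95)}
        fit = pf.gene_fitness(make_strain_matrix(vals, prov))
        assert fit.loc["gA", "e1"] == pytest.approx(-3.0)

    def test_dual_pool_strain_contributes_two_measurements(self):
        vals = {("s1", "up"): {"e1": -1.0}, ("s1", "dn"): {"e1": -1.2}}
        prov = {("s1", "up"): ("chromosome", "P1", "gA", 0.5),
                ("s1", "dn"): ("chromosome", "P1", "gA", 0.5)}
        m = make_strain_matrix(vals, prov)
        meas = gs.gene_measurements(m)
        assert meas.mean.loc["gA", "e1"] == pytest.approx(-1.1)
        assert meas.n.loc["gA", "e1"] == 2

    def test_brute_force_equivalence(self, fitness_matrix):
        """Recompute gene fitness from the strain table by hand."""
        meas = gs.gene_measurements(fitness_matrix)
        prov = fitness_matrix.provenance
        vals = fitness_matrix.values
        rng = np.random.default_rng(0)
        genes = rng.choice(meas.mean.index, size=25, replace=False)
        for gene in genes:
            rows = prov[prov["gene_id"] == gene]
            good = rows[rows["gene_fraction"].between(0.05, 0.80)]
            use = good if len(good) else rows
            for exp in vals.columns[:4]:
                expected = vals.loc[use.index, exp].dropna()
                got = meas.mean.loc[gene, exp]
                if len(expected) == 0:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected.mean(), abs=1e-12)


class TestModeratedT:
    def test_zero_mean_gives_zero_t(self):
        assert gs.moderated_t(0.0, 4, 1.3, 0.5) == 0.0

    def test_two_measurement_example(self):
        # x = {1, 1}: mu=1, s=0, n=2
        assert gs.moderated_t(1.0, 2, 0.0, 0.5) == pytest.approx(np.sqrt(2) / 0.5)

    def test_singleton_rule(self):
        assert gs.moderated_t(-0.6, 1, 0.0, 0.3) == pytest.approx(-2.0)

    def test_psi_must_be_positive(self):
        with pytest.raises(CalibrationError):
            gs.moderated_t(1.0, 2, 0.1, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-5, 5), st.floats(-5, 5),
           st.integers(1, 10), st.floats(0, 2), st.floats(0.01, 2))
    def test_monotone_in_mean(self, mu1, mu2, n, s, psi):
        t1 = gs.moderated_t(mu1, n, s if n > 1 else 0.0, psi)
        t2 = gs.moderated_t(mu2, n, s if n > 1 else 0.0, psi)
        if mu1 < mu2:
            assert t1 <= t2


class TestPsi:
    def _measurements(self, sds, ns):
        mean = pd.DataFrame({"e1": [0.0] * len(sds)})
        sd = pd.DataFrame({"e1": sds})
        n = pd.DataFrame({"e1": ns})
        return gs.GeneMeasurements(mean=mean, sd=sd, n=n,
                                   good_only=pd.Series(dtype=bool))

    def test_median_of_sds(self):
        meas = self._measurements([0.2, 0.4, 0.6], [2, 2, 3])
        assert gs.compute_psi(meas) == pytest.approx(0.4)

    def test_even_count_median_is_midpoint(self):
        meas = self._measurements([0.2, 0.4], [2, 2])
        assert gs.compute_psi(meas) == pytest.approx(0.3)

    def test_singletons_do_not_contribute(self):
        meas = self._measurements([0.0, 0.4], [1, 2])
        assert gs.compute_psi(meas) == pytest.approx(0.4)

    def test_no_multi_measurement_genes_raises(self):
        meas = self._measurements([0.0, 0.0], [1, 1])
        with pytest.raises(CalibrationError):
            gs.compute_psi(meas)


def _control_frames(values_by_n, controls=("c1", "c2")):
    """Build T and n frames whose control columns hold the given values."""
    rows_t, rows_n = [], []
    for n_meas, values in values_by_n.items():
        for v in values:
            rows_t.append({c: v for c in controls})
            rows_n.append({c: n_meas for c in controls})
    t = pd.DataFrame(rows_t)
    n = pd.DataFrame(rows_n)
    return t, n


class TestCalibration:
    def test_stratum_median_maps_to_zero(self):
        rng = np.random.default_rng(7)
        draws = rng.normal(size=500)
        t = pd.DataFrame({"c1": draws[:250], "c2": draws[250:]})
        n = pd.DataFrame(2, index=t.index, columns=t.columns)
        cal = gs.calibrate_null(t, n, ["c1", "c2"], psi=0.3)
        st_ = cal.stratum_for(2)
        z = st_.z(np.array([np.median(draws)]))
        assert abs(z[0]) < 0.01

    def test_standard_normal_controls_recover_quantiles(self):
        rng = np.random.default_rng(11)
        draws = rng.normal(size=10_000)
        t = pd.DataFrame({"c1": draws[:5000], "c2": draws[5000:]})
        n = pd.DataFrame(4, index=t.index, columns=t.columns)
        cal = gs.calibrate_null(t, n, ["c1", "c2"], psi=0.3)
        z = cal.stratum_for(4).z(np.array([1.96]))
        assert 1.8 <= z[0] <= 2.1

    def test_sparse_stratum_is_merged_with_warning(self, caplog):
        rng = np.random.default_rng(13)
        t, n = _control_frames({1: rng.normal(size=5), 4: rng.normal(size=100)})
        with caplog.at_level("WARNING"):
            cal = gs.calibrate_null(t, n, ["c1", "c2"], psi=0.3)
        assert any("merged" in r.message for r in caplog.records)
        # n=1 and the higher strata are served by a shared map
        assert cal.stratum_for(1) is cal.stratum_for(4)

    def test_fewer_than_two_controls_raises(self):
        t = pd.DataFrame({"c1": np.zeros(100)})
        n = pd.DataFrame(2, index=t.index, columns=t.columns)
        with pytest.raises(CalibrationError):
            gs.calibrate_null(t, n, ["c1"], psi=0.3)

    def test_z_map_is_monotone_including_tails(self):
        rng = np.random.default_rng(17)
        t = pd.DataFrame({"c1": rng.normal(size=300), "c2": rng.normal(size=300)})
        n = pd.DataFrame(1, index=t.index, columns=t.columns)
        cal = gs.calibrate_null(t, n, ["c1", "c2"], psi=0.3)
        grid = np.linspace(-8, 8, 401)  # extends beyond the observed range
        z = cal.stratum_for(1).z(grid)
        assert (np.diff(z) >= 0).all()
        assert np.isfinite(z).all()


class TestPhenotypeTest:
    def test_all_zero_z_is_null(self):
        z = pd.DataFrame(np.zeros((1, 10)), index=["gA"],
                         columns=[f"e{i}" for i in range(10)])
        res = pf.phenotype_test(z, list(z.columns))
        assert res.loc["gA", "chisq"] == 0.0
        assert res.loc["gA", "pvalue"] == pytest.approx(1.0)
        assert not res.loc["gA", "significant"]

    def test_single_z_closed_form(self):
        z = pd.DataFrame({"e1": [2.0]}, index=["gA"])
        res = pf.phenotype_test(z, ["e1"])
        assert res.loc["gA", "df"] == 1
        assert res.loc["gA", "pvalue"] == pytest.approx(2 * stats.norm.cdf(-2), rel=1e-6)

    def test_missing_z_reduces_df(self):
        z = pd.DataFrame({"e1": [1.0], "e2": [np.nan]}, index=["gA"])
        res = pf.phenotype_test(z, ["e1", "e2"])
        assert res.loc["gA", "df"] == 1

    def test_alpha_domain(self):
        z = pd.DataFrame({"e1": [1.0]}, index=["gA"])
        with pytest.raises(ParameterError):
            pf.phenotype_test(z, ["e1"], alpha=1.5)


class TestBonferroniThreshold:
    @pytest.mark.parametrize("alpha, n, expected, tol", [
        (0.5, 1, 0.0, 1e-9),
        (0.05, 1, -1.6449, 1e-3),
        (0.01, 195, -3.88, 0.01),
    ])
    def test_quantiles(self, alpha, n, expected, tol):
        assert pf.bonferroni_z_threshold(alpha, n) == pytest.approx(expected, abs=tol)

    def test_domain(self):
        with pytest.raises(ParameterError):
            pf.bonferroni_z_threshold(0.0, 10)


class TestStrongPattern:
    def _tests(self, chisqs):
        return pd.DataFrame({
            "chisq": chisqs, "df": 5, "pvalue": 0.5, "significant": False,
        }, index=[f"g{i}" for i in range(len(chisqs))])

    def test_top_third_by_chisq(self):
        tests = self._tests([10.0, 20.0, 30.0])
        z = pd.DataFrame(0.0, index=tests.index, columns=["e1"])
        strong = pf.strong_pattern_genes(tests, z, z_threshold=-3.88)
        assert set(strong) == {"g2"}

    def test_extreme_single_z_included(self):
        tests = self._tests([1.0, 20.0, 30.0])
        z = pd.DataFrame({"e1": [-5.0, 0.0, 0.0]}, index=tests.index)
        strong = pf.strong_pattern_genes(tests, z, z_threshold=-3.88)
        assert "g0" in strong

    def test_null_genes_yield_about_a_third(self):
        rng = np.random.default_rng(23)
        tests = self._tests(list(rng.chisquare(5, size=90)))
        z = pd.DataFrame(0.0, index=tests.index, columns=["e1"])
        strong = pf.strong_pattern_genes(tests, z, z_threshold=-3.88)
        assert len(strong) == 30

    def test_boundary_ties_are_all_included(self):
        tests = self._tests([30.0, 30.0, 30.0, 1.0, 2.0, 3.0])
        z = pd.DataFrame(0.0, index=tests.index, columns=["e1"])
        strong = pf.strong_pattern_genes(tests, z, z_threshold=-3.88)
        assert set(strong) == {"g0", "g1", "g2"}


class TestSignificantChanges:
    def test_class_counting(self):
        fitness = pd.DataFrame({"e1": [-2.5], "e2": [-2.5], "e3": [1.5]},
                               index=["gA"])
        z = pd.DataFrame({"e1": [-4.0], "e2": [-1.0], "e3": [3.0]}, index=["gA"])
        counts = pf.count_significant_changes(fitness, z)
        row = counts.loc["gA"]
        # e1 counts in sick1 and sick2 (not sick3); e2 fails the Z gate;
        # e3 is a positive change
        assert (row["n_sick1"], row["n_sick2"], row["n_sick3"], row["n_positive"]) \
            == (1, 1, 0, 1)


class TestEndToEndScores:
    def test_in_sample_control_z_is_standardized(self, scores, dataset):
        zc = scores.z[dataset["truth"].controls].to_numpy().ravel()
        zc = zc[np.isfinite(zc)]
        assert abs(zc.mean()) < 0.1
        assert 0.9 < zc.std() < 1.1

    def test_seeded_effects_are_detected(self, scores, dataset):
        truth = dataset["truth"]
        strong_truth = truth.matrix[truth.conditions].abs().max(axis=1) >= 3.0
        hit_genes = [g for g in strong_truth[strong_truth].index
                     if g in scores.phenotypes.index]
        sens = scores.phenotypes.loc[hit_genes, "significant"].mean()
        assert sens > 0.8
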