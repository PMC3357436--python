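"""Association fits, instrument-strength metrics, QC and selection logic."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy import stats

from vitdmr import assoc
from vitdmr.assoc import (
    QcThresholds,
    SnpQcStats,
    f_statistic,
    fit_linear_assoc,
    hwe_test,
    interaction_test,
    qc_filter,
    relative_bias,
    select_instruments,
)
from vitdmr.synthdata import SnpSpec, simulate_genotypes


class TestFitLinearAssoc:
    def test_noiseless_line(self):
        g = np.array([0, 0, 1, 1, 2, 2], float)
        res = fit_linear_assoc(2.0 * g, g)
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_six_point_fixture_slope(self):
        # hand-computed OLS slope: cov(g,y)/var(g) = 0.5
        g = np.array([0, 0, 1, 1, 2, 2], float)
        y = np.array([1.0, 1.2, 1.5, 1.7, 2.0, 2.2])
        res = fit_linear_assoc(y, g)
        assert res.beta == pytest.approx(0.5, abs=1e-12)

    def test_constant_response_degenerate_safe(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1], float)
        res = fit_linear_assoc(np.ones_like(g), g)
        assert res.beta == 0.0
        assert res.p == 1.0
        assert res.weak

    def test_monomorphic_snp_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            fit_linear_assoc(np.arange(10.0), np.zeros(10))

    def test_major_allele_dosage_flipped_to_minor(self):
        rng = np.random.default_rng(0)
        g_minor = rng.binomial(2, 0.2, 2000).astype(float)
        y = -0.1 * g_minor + rng.normal(0, 0.3, 2000)
        res_major = fit_linear_assoc(y, 2.0 - g_minor)
        res_minor = fit_linear_assoc(y, g_minor)
        assert res_major.beta == pytest.approx(res_minor.beta, abs=1e-12)
        assert res_major.maf == pytest.approx(res_minor.maf, abs=1e-12)

    def test_complete_case_n_reported(self):
        g = np.array([0, 1, 2, np.nan, 1, 0], float)
        y = np.array([1.0, 1.1, 0.9, 1.2, np.nan, 1.0])
        res = fit_linear_assoc(y, g)
        assert res.n == 4

    def test_wald_type_i_error_calibrated(self):
        """Null simulations: fraction of p < 0.05 within [0.03, 0.07]."""
        rng = np.random.default_rng(99)
        hits = 0
        sims = 1000
        for _ in range(sims):
            g = rng.binomial(2, 0.3, 300).astype(float)
            y = rng.normal(0, 1, 300)
            hits += fit_linear_assoc(y, g).p < 0.05
        assert 0.03 <= hits / sims <= 0.07


class TestFStatistic:
    def test_zero_r2(self):
        assert f_statistic(0.0, 100) == 0.0

    def test_printed_scale_value(self):
        # R^2 = 1.18% at n = 6027 gives F ~ 71.9 from the formula
        assert f_statistic(0.0118, 6027) == pytest.approx(71.95, abs=0.05)

    def test_rejects_r2_of_one(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 100)

    def test_equals_regression_f(self):
        """Formula F equals the fitted simple-regression F to 1e-8."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(30, 500))
            g = rng.binomial(2, rng.uniform(0.05, 0.5), n).astype(float)
            if np.var(g) == 0:
                continue
            y = rng.normal(0, 1, n) + rng.uniform(-0.3, 0.3) * g
            fit = sm.OLS(y, sm.add_constant(g)).fit()
            assert f_statistic(fit.rsquared, n) == pytest.approx(
                fit.fvalue, rel=1e-8)


class TestRelativeBias:
    @pytest.mark.parametrize("f,expected", [(73.4, 1.4), (63.1, 1.6), (100.0, 1.0)])
    def test_printed_values(self, f, expected):
        assert relative_bias(f) == expected

    def test_undefined_below_f_floor(self):
        assert relative_bias(1.5) is None
        assert relative_bias(1.89) is None

    @given(st.floats(min_value=2.0, max_value=5e3))
    def test_non_increasing_in_f(self, f):
        assert relative_bias(1.5 * f) <= relative_bias(f)

    def test_weak_flag_flips_at_f_ten(self):
        rng = np.random.default_rng(17)
        flags = []
        for effect in (0.02, 0.25):
            g = rng.binomial(2, 0.3, 800).astype(float)
            y = effect * g + rng.normal(0, 1, 800)
            res = fit_linear_assoc(y, g)
            assert res.weak == (res.f_stat < 10.0)
            flags.append(res.weak)
        assert flags == [True, False]


class TestHweTest:
    def test_exact_hwe_proportions(self):
        p = hwe_test((49, 42, 9))
        assert p > 0.99

    def test_complete_heterozygote_deficit(self):
        assert hwe_test((50, 0, 50)) < 1e-10

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hwe_test((0, 0, 0))

    def test_agrees_with_scipy_chisquare_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = rng.integers(1, 200, size=3)
            n = counts.sum()
            p_hat = (2 * counts[2] + counts[1]) / (2 * n)
            expected = n * np.array(
                [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat ** 2])
            chi2, _ = stats.chisquare(counts, expected, ddof=1)
            assert hwe_test(tuple(counts)) == pytest.approx(
                stats.chi2.sf(chi2, 1), rel=1e-10)


class TestQcFilter:
    def test_low_maf_fails(self):
        out = qc_filter([SnpQcStats("a", 0.005, 0.95, 0.5)])
        assert not out.loc[0, "passed"] and "MAF" in out.loc[0, "reasons"]

    def test_call_rate_boundary(self):
        fail = qc_filter([SnpQcStats("a", 0.2, 0.79, 0.5)])
        ok = qc_filter([SnpQcStats("a", 0.2, 0.81, 0.5)])
        assert not fail.loc[0, "passed"] and "call_rate" in fail.loc[0, "reasons"]
        assert ok.loc[0, "passed"]

    def test_exact_boundaries_fail_strictly(self):
        t = QcThresholds()
        out = qc_filter([SnpQcStats("a", t.maf_min, t.call_rate_min, t.hwe_p_min)])
        assert set(out.loc[0, "reasons"].split(",")) == {"HWE", "MAF", "call_rate"}


class TestSelectInstruments:
    def _results(self):
        def r(sid, p, gene):
            return assoc.AssociationResult(sid, 5000, 0.2, -0.05, 0.01, p,
                                           0.01, 50.0, 2.0, False, gene)
        return [
            r("rs_gwa", 0.016, "GC"),
            r("rs_oca2", 0.002, "OCA2"),
            r("rs_cyp27b1", 0.008, "CYP27B1"),
            r("rs_cyp27a1", 0.55, "CYP27A1"),
        ]

    def test_selection_statuses(self):
        out = select_instruments(
            self._results(),
            gene_map={}, gwa_default_snps={"rs_gwa"}, n_candidate_genes=7,
            replication_flags={"rs_cyp27b1"},
        ).set_index("snp_id")
        assert out.loc["rs_gwa", "status"] == "selected_default"
        assert out.loc["rs_oca2", "status"] == "selected"
        assert out.loc["rs_cyp27b1", "status"] == "borderline"
        assert out.loc["rs_cyp27a1", "status"] == "excluded"
        assert out["threshold"].iloc[0] == pytest.approx(0.05 / 7)

    def test_borderline_requires_replication_flag(self):
        out = select_instruments(self._results(), {}, {"rs_gwa"}, 7).set_index("snp_id")
        assert out.loc["rs_cyp27b1", "status"] == "excluded"

    def test_invalid_gene_count(self):
        with pytest.raises(ValueError):
            select_instruments(self._results(), {}, set(), 0)


class TestInteractionTest:
    def test_threshold_from_bonferroni_m(self):
        rng = np.random.default_rng(1)
        g1 = rng.binomial(2, 0.3, 3000).astype(float)
        g2 = rng.binomial(2, 0.4, 3000).astype(float)
        y = 0.3 * g1 * g2 + rng.normal(0, 0.5, 3000)
        p, flagged = interaction_test(y, g1, g2, bonferroni_m=5)
        assert flagged and p < 0.01  # 0.05/5

    def test_null_interaction_calibrated(self):
        rng = np.random.default_rng(2)
        hits = 0
        sims = 400
        for _ in range(sims):
            g1 = rng.binomial(2, 0.3, 400).astype(float)
            g2 = rng.binomial(2, 0.4, 400).astype(float)
            y = 0.1 * g1 - 0.1 * g2 + rng.normal(0, 0.5, 400)
            p, _ = interaction_test(y, g1, g2)
            hits += p < 0.05
        assert 0.03 <= hits / sims <= 0.07

    def test_collinear_product_rejected(self):
        a = np.array([0.0, 1.0] * 50)
        with pytest.raises(ValueError, match="collinear"):
            interaction_test(np.random.default_rng(0).normal(size=100), a, a)


def test_association_table_layout(big_cohort):
    gm, cohort = big_cohort
    table = assoc.association_table(gm, cohort)
    assert list(table.columns) == [
        "gene", "snp", "n", "maf", "beta", "se", "p",
        "pct_variance", "f_stat", "relative_bias_pct"]
    assert len(table) == 5
    gc = table.set_index("snp").loc["rs4588"]
    assert gc["beta"] == pytest.approx(-0.08, abs=0.02)
    assert gc["f_stat"] > 10
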