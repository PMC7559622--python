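"""Genetic association models: collapses, Woolf odds ratios, the
grouped-binomial additive trend fit, HWE, and their symmetries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import expit

from pocdkit import (
    GenotypeTable,
    ModelError,
    Table2x2,
    additive_trend_or,
    association_report,
    chi_square_test,
    collapse,
    hwe_chi_square,
    odds_ratio_2x2,
)
from pocdkit.association import (
    Z95,
    _grouped_logistic_loglik,
    format_estimate,
)
from pocdkit.datasets import consistency_report


def grid_search_additive(table: GenotypeTable, center: float,
                         half_width: float = 1e-3, points: int = 2001) -> float:
    """Independent maximizer of the grouped binomial likelihood: profile
    b0 (by root-finding its monotone score equation) over a fine b1 grid."""
    g = np.array([0.0, 1.0, 2.0])
    n = np.array(table.genotype_totals, dtype=float)
    y = np.array(table.cases, dtype=float)

    def profile_loglik(b1: float) -> float:
        def score_b0(b0: float) -> float:
            return float(y.sum() - (n * expit(b0 + b1 * g)).sum())

        b0 = brentq(score_b0, -50.0, 50.0)
        return _grouped_logistic_loglik(b0, b1, g, y, n)

    grid = np.linspace(center - half_width, center + half_width, points)
    vals = [profile_loglik(b) for b in grid]
    return float(grid[int(np.argmax(vals))])


class TestCollapse:
    def test_dominant_recessive_allelic_cells(self, day7_table):
        assert collapse(day7_table, "dominant").cells == (19, 59, 10, 11)
        assert collapse(day7_table, "recessive").cells == (3, 20, 26, 50)
        assert collapse(day7_table, "allelic").cells == (22, 79, 36, 61)

    def test_allele_counts_match_published_columns(self, day7_table,
                                                   month3_table):
        assert day7_table.allele_counts(day7_table.cases) == (36, 22)
        assert day7_table.allele_counts(day7_table.noncases) == (61, 79)
        assert month3_table.allele_counts(month3_table.cases) == (28, 22)
        assert month3_table.allele_counts(month3_table.noncases) == (69, 79)


class TestOddsRatio2x2:
    def test_published_dominant_day7(self):
        r = odds_ratio_2x2(Table2x2(19, 59, 10, 11))
        assert round(r.or_point, 2) == 0.35
        assert round(r.ci95[0], 2) == 0.13
        assert round(r.ci95[1], 2) == 0.96

    def test_published_recessive_day7(self):
        r = odds_ratio_2x2(Table2x2(3, 20, 26, 50))
        assert round(r.or_point, 2) == 0.29
        assert format_estimate(r.ci95[0]) == "0.078"
        assert round(r.ci95[1], 2) == 1.06

    def test_balanced_table_is_null(self):
        r = odds_ratio_2x2(Table2x2(8, 8, 8, 8))
        assert r.or_point == pytest.approx(1.0)
        assert r.ci95[0] * r.ci95[1] == pytest.approx(1.0)  # symmetric in log
        assert r.p == pytest.approx(1.0)

    def test_haldane_only_on_zero_cells(self):
        r = odds_ratio_2x2(Table2x2(0, 10, 5, 5))
        assert r.correction_applied
        assert odds_ratio_2x2(Table2x2(1, 10, 5, 5)).correction_applied is False

    def test_undefined_or_raises(self):
        with pytest.raises(ModelError):
            odds_ratio_2x2(Table2x2(0, 0, 5, 5))

    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_woolf_ci_identity_and_swaps(self, cells):
        """log(hi) - log(lo) = 2 * 1.96 * SE exactly; swapping exposure
        columns or status rows maps OR -> 1/OR and reflects the CI."""
        a, b, c, d = cells
        r = odds_ratio_2x2(Table2x2(a, b, c, d))
        assert math.log(r.ci95[1]) - math.log(r.ci95[0]) == pytest.approx(
            2 * Z95 * r.se_log_or, rel=1e-12)
        for swapped in (Table2x2(c, d, a, b), Table2x2(b, a, d, c)):
            s = odds_ratio_2x2(swapped)
            assert s.or_point == pytest.approx(1.0 / r.or_point, rel=1e-12)
            assert s.ci95[0] == pytest.approx(1.0 / r.ci95[1], rel=1e-12)
            assert s.ci95[1] == pytest.approx(1.0 / r.ci95[0], rel=1e-12)
            assert s.p == pytest.approx(r.p, rel=1e-9)


class TestAdditiveTrend:
    def test_published_day7_or(self, day7_table):
        r = additive_trend_or(day7_table)
        assert round(r.or_point, 2) == 0.41
        assert round(r.ci95[0], 1) == 0.2
        assert round(r.ci95[1], 2) == 0.84

    def test_no_trend_gives_unit_or(self):
        t = GenotypeTable(cases=(10, 20, 30), noncases=(20, 40, 60))
        r = additive_trend_or(t)
        assert r.or_point == pytest.approx(1.0, abs=1e-9)

    def test_empty_genotype_class_reduces_to_2x2(self):
        """With one empty genotype column the saturated two-group logistic
        equals the closed-form 2x2 OR (allele coding 0 vs 1)."""
        t = GenotypeTable(cases=(12, 7, 0), noncases=(30, 9, 0))
        r = additive_trend_or(t)
        exact = (7 * 30) / (9 * 12)
        assert r.or_point == pytest.approx(exact, rel=1e-9)

    def test_matches_statsmodels_glm(self, day7_table, month3_table):
        """Cross-check the hand-rolled Newton-Raphson against an
        independent GLM implementation."""
        sm = pytest.importorskip("statsmodels.api")
        for t in (day7_table, month3_table):
            y = np.column_stack([t.cases, np.array(t.noncases)])
            X = sm.add_constant(np.array([0.0, 1.0, 2.0]))
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            r = additive_trend_or(t)
            # tolerances reflect GLM's looser IRLS stopping rule
            assert r.log_or == pytest.approx(fit.params[1], abs=1e-6)
            assert r.se_log_or == pytest.approx(fit.bse[1], abs=1e-5)

    def test_mle_matches_grid_search(self, day7_table):
        b1 = additive_trend_or(day7_table).log_or
        assert abs(grid_search_additive(day7_table, b1) - b1) <= 1.1e-6

    def test_separation_raises(self):
        with pytest.raises(ModelError):
            additive_trend_or(GenotypeTable(cases=(0, 0, 10),
                                            noncases=(10, 10, 0)))

    def test_single_class_rank_deficient(self):
        with pytest.raises(ModelError):
            additive_trend_or(GenotypeTable(cases=(5, 0, 0),
                                            noncases=(5, 0, 0)))


class TestHWE:
    def test_perfect_equilibrium(self):
        assert hwe_chi_square((25, 50, 25)).chi2 == pytest.approx(0.0)

    def test_maximal_disequilibrium(self):
        r = hwe_chi_square((50, 0, 50))
        assert r.chi2 == pytest.approx(100.0)

    def test_pooled_patient_counts(self):
        """The pooled day-7 genotype counts give chi2 ~= 1.23 (p ~= 0.27),
        not the published 4.402."""
        r = hwe_chi_square((21, 55, 23))
        assert r.chi2 == pytest.approx(1.232, abs=0.001)
        assert r.p == pytest.approx(0.267, abs=0.001)
        assert r.df == 1
        assert sum(r.expected) == pytest.approx(99.0, abs=1e-9)

    def test_monomorphic_warns(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            r = hwe_chi_square((40, 0, 0))
        assert r.chi2 == 0.0


class TestChiSquare:
    def test_null_table(self):
        stat, df, p = chi_square_test(Table2x2(10, 10, 10, 10))
        assert (stat, df) == (0.0, 1) and p == pytest.approx(1.0)

    def test_dominant_day7_significant(self):
        _, _, p = chi_square_test(Table2x2(19, 59, 10, 11))
        assert p < 0.05

    def test_genotype_table_has_two_df(self, day7_table):
        _, df, _ = chi_square_test(day7_table)
        assert df == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ModelError):
            chi_square_test(np.array([[0, 0], [3, 4]]))


class TestReportAndDiagnostics:
    def test_published_month3_values(self, day7_table, month3_table):
        rep = association_report(day7_table, month3_table)
        get = lambda tp, m: rep[(rep.timepoint == tp) & (rep.model == m)].iloc[0]
        assert get("3 months", "dominant")["OR_95CI"] == "0.45 (0.16-1.27)"
        assert get("3 months", "allelic")["OR_95CI"].startswith("0.69")
        assert get("3 months", "recessive")["OR_95CI"].endswith("2.37)")

    def test_significance_flags_match_narrative(self, day7_table, month3_table):
        """At day 7 the additive and dominant models are significant
        (CI excludes 1); the recessive and every month-3 model are not."""
        rep = association_report(day7_table, month3_table)
        sig = rep[rep.model != "HWE"].set_index(["timepoint", "model"])[
            "significant"]
        assert sig[("7 days", "additive")] and sig[("7 days", "dominant")]
        assert not sig[("7 days", "recessive")]
        assert not sig.loc["3 months"].any()

    def test_model_failures_do_not_abort_report(self):
        t = GenotypeTable(cases=(0, 0, 10), noncases=(10, 10, 0))
        rep = association_report(t)
        assert (rep[rep.model == "additive"]["error"].iloc[0] != "")
        assert (rep[rep.model == "dominant"]["error"].iloc[0] == "")

    def test_known_published_inconsistencies_are_flagged(self):
        """The bundled counts audit flags exactly the irreproducible
        published values: day-7 allelic OR (0.67 vs computed ~0.47), the
        HWE statistic (4.402 vs computed ~1.23), the malformed month-3
        additive CI, and the month-3 group-size mismatch."""
        flags = {(d.timepoint, d.quantity): d for d in consistency_report()}
        allelic = flags[("7 days", "allelic OR")]
        assert allelic.computed == pytest.approx(0.47, abs=0.005)
        hwe = flags[("7 days", "HWE chi2")]
        assert hwe.published == 4.402
        assert hwe.computed == pytest.approx(1.232, abs=0.001)
        assert ("3 months", "additive 95% CI") in flags
        assert ("7 days", "allelic 95% CI") in flags
        assert ("3 months", "allelic 95% CI") in flags
        assert flags[("3 months", "group sizes")].computed == (25, 74)
        # the reproducible ORs must NOT be flagged
        assert ("7 days", "dominant OR") not in flags
        assert ("7 days", "additive OR") not in flags
        assert ("3 months", "recessive OR") not in flags
        assert ("7 days", "dominant 95% CI") not in flags
        assert ("3 months", "recessive 95% CI") not in flags


class TestSimulationRecovery:
    def test_additive_or_recovered_from_simulation(self):
        """A large simulated cohort with per-allele log-OR -0.9 yields an
        additive OR estimate in [0.33, 0.50] (truth exp(-0.9) ~= 0.41)."""
        from pocdkit import SimConfig, generate_cohort
        from scipy.special import logit

        cfg = SimConfig(n_patients=4000, n_controls=0, beta_per_g=-0.9,
                        intercept_logit=float(logit(0.48)), seed=21)
        df = generate_cohort(cfg)
        t = GenotypeTable.from_subjects(df.genotype, df.truth_insult)
        assert 0.33 <= additive_trend_or(t).or_point <= 0.50
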