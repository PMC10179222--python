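"""Cohort analytics: prevalence rounding and CIs, correlation/regression,
group comparisons, exact tests and the covariate report."""

import numpy as np
import pytest
from scipy import stats

from cflus.agreement import ContingencyTable2x2
from cflus.cohort import (
    ALL_SIGNS,
    compare_two_groups,
    fisher_association,
    kruskal_wallis_by_category,
    pearson_with_regression,
    percentage,
    prevalence_table,
    score_vs_covariates_report,
    sign_present,
    wilson_ci,
)
from cflus.simulate import GeneratorConfig, generate_cohort


class TestPercentageAndCI:
    @pytest.mark.parametrize(
        "n_with,n_total,pct",
        [
            # study-group sign prevalences, count over 131
            (123, 131, 94), (108, 131, 82), (130, 131, 99), (36, 131, 27),
            (7, 131, 5), (57, 131, 44), (95, 131, 73), (84, 131, 64),
            (38, 131, 29), (32, 131, 24), (53, 131, 40),
            # control group over 32
            (17, 32, 53), (15, 32, 47), (23, 32, 72), (5, 32, 16),
            (2, 32, 6), (3, 32, 9), (0, 32, 0),
            # conditional fraction
            (35, 36, 97),
        ],
    )
    def test_round_to_nearest_reproduces_printed_percentages(self, n_with, n_total, pct):
        assert percentage(n_with, n_total) == pct

    def test_wilson_matches_r_prop_test(self):
        """Both Wilson variants equal R's prop.test confidence intervals
        (correct=FALSE / correct=TRUE)."""
        lo, hi = wilson_ci(36, 131)
        assert lo == pytest.approx(0.2056028285, abs=1e-9)
        assert hi == pytest.approx(0.3568462838, abs=1e-9)
        lo, hi = wilson_ci(123, 131)
        assert lo == pytest.approx(0.8841196490, abs=1e-9)
        assert hi == pytest.approx(0.9687337761, abs=1e-9)
        lo, hi = wilson_ci(36, 131, continuity=True)
        assert lo == pytest.approx(0.2022126787, abs=1e-9)
        assert hi == pytest.approx(0.3608656101, abs=1e-9)
        lo, hi = wilson_ci(123, 131, continuity=True)
        assert lo == pytest.approx(0.8793340960, abs=1e-9)
        assert hi == pytest.approx(0.9713263837, abs=1e-9)

    def test_ci_contains_point_estimate_and_stays_in_unit_interval(self):
        for n_with, n_total in [(0, 32), (32, 32), (1, 5), (36, 131), (64, 131)]:
            lo, hi = wilson_ci(n_with, n_total)
            assert 0.0 <= lo <= n_with / n_total <= hi <= 1.0


class TestPrevalenceTable:
    def test_counts_patients_not_fields(self, rng):
        cohort = generate_cohort(GeneratorConfig(n_patients=40, seed=2))
        rows = prevalence_table(cohort, signs=["i_lines"])
        (row,) = rows
        assert row.n_total == 40
        assert row.n_with == sum(sign_present(r, "i_lines") for r in cohort)
        assert row.pct == percentage(row.n_with, row.n_total)
        assert row.ci_low <= row.n_with / row.n_total <= row.ci_high

    def test_zero_prevalence_row(self):
        cohort = generate_cohort(GeneratorConfig(n_patients=32, group="control", seed=3))
        rows = {r.sign: r for r in prevalence_table(cohort, signs=["am_lines"])}
        assert rows["am_lines"].n_with == 0
        assert rows["am_lines"].pct == 0
        assert rows["am_lines"].ci_low == 0.0

    def test_unknown_sign_rejected(self, vacuous_record):
        with pytest.raises(ValueError, match="unknown sign"):
            prevalence_table([vacuous_record], signs=["x_lines"])

    def test_all_signs_covered(self, vacuous_record):
        rows = prevalence_table([vacuous_record], signs=ALL_SIGNS)
        assert len(rows) == len(ALL_SIGNS)


class TestCorrelation:
    def test_exact_linear_relation(self):
        x = np.arange(1.0, 8.0)
        res = pearson_with_regression(x, 3 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.guilford_label == "very high"

    def test_orthogonal_vectors_give_zero(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, -1.0, 0.0, 1.0])
        assert pearson_with_regression(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_matches_moment_formulas(self, rng):
        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0, 1, 50)
        res = pearson_with_regression(x, y)
        sxy = np.mean(x * y) - x.mean() * y.mean()
        r = sxy / (x.std() * y.std())
        assert res.r == pytest.approx(r, abs=1e-10)
        assert res.slope == pytest.approx(sxy / np.var(x), abs=1e-10)
        assert res.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_constant_input_flagged(self):
        res = pearson_with_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate


class TestGroupComparisons:
    def test_fully_separated_small_groups_exact_p(self):
        res = compare_two_groups([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], policy="mww")
        assert res.test_used == "mann_whitney"
        assert res.p_value == pytest.approx(0.1)  # 2 * 1/C(6,3)

    def test_identical_groups_p_one(self):
        res = compare_two_groups([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1], policy="mww")
        assert res.p_value == pytest.approx(1.0)

    def test_auto_policy_picks_t_for_gaussian_samples(self, rng):
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)])
        labels = np.repeat([0, 1], 40)
        res = compare_two_groups(x, labels, policy="auto")
        assert res.test_used == "t_test"

    def test_auto_policy_falls_back_to_mww_for_skewed_samples(self, rng):
        x = np.concatenate([rng.lognormal(0, 1.5, 60), rng.lognormal(0.5, 1.5, 60)])
        labels = np.repeat([0, 1], 60)
        assert compare_two_groups(x, labels, policy="auto").test_used == "mann_whitney"

    def test_mww_invariant_to_monotone_transform(self, rng):
        x = rng.normal(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        if labels.sum() < 2 or labels.sum() > 28:
            labels[:3] = [0, 1, 0]
        p1 = compare_two_groups(x, labels, policy="mww").p_value
        p2 = compare_two_groups(np.exp(x), labels, policy="mww").p_value
        assert p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_two_groups([1, 2, 3], [0, 0, 1])

    def test_kruskal_identical_groups_h_zero(self):
        res = kruskal_wallis_by_category([1, 2, 1, 2, 1, 2], ["a", "a", "b", "b", "c", "c"])
        assert res.statistic == pytest.approx(0.0)

    def test_kruskal_matches_rank_arithmetic(self):
        # groups (1,2),(3,4),(5,6): rank sums 3, 7, 11 ->
        # H = 12/(6*7) * (3^2/2 + 7^2/2 + 11^2/2) - 3*7 = 3.714285...
        res = kruskal_wallis_by_category([1, 2, 3, 4, 5, 6], list("aabbcc"))
        assert res.statistic == pytest.approx(12 / 42 * (9 / 2 + 49 / 2 + 121 / 2) - 21)
        assert res.test_used == "kruskal_wallis"

    def test_tie_correction_raises_h(self):
        values = [1, 1, 1, 2, 2, 3, 3, 3, 4]
        cats = list("aaabbcccb")
        corrected = kruskal_wallis_by_category(values, cats).statistic
        # uncorrected H from the same rank sums
        ranks = stats.rankdata(values)
        n = len(values)
        h_unc = 12 / (n * (n + 1)) * sum(
            ranks[[i for i, c in enumerate(cats) if c == g]].sum() ** 2
            / sum(c == g for c in cats)
            for g in "abc"
        ) - 3 * (n + 1)
        assert corrected >= h_unc

    def test_two_categories_routed_away(self):
        with pytest.raises(ValueError, match="compare_two_groups"):
            kruskal_wallis_by_category([1, 2, 3, 4], ["a", "a", "b", "b"])


class TestFisher:
    def test_association_reconstruction_is_significant(self):
        res = fisher_association(ContingencyTable2x2(35, 1, 60, 35))
        assert res.fisher_p < 0.0001

    def test_independent_proportions_p_one(self):
        assert fisher_association(ContingencyTable2x2(10, 10, 10, 10)).fisher_p == pytest.approx(1.0)

    def test_extreme_diagonal_table_both_conventions(self):
        t = ContingencyTable2x2(5, 0, 0, 5)
        assert fisher_association(t, "minlike").fisher_p == pytest.approx(2 / 252)
        assert fisher_association(t, "doubling").fisher_p == pytest.approx(2 / 252)
        assert fisher_association(t).odds_ratio == np.inf

    def test_invariant_to_transpose(self, rng):
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, 4))
            if a + b + c + d == 0:
                continue
            t = ContingencyTable2x2(a, b, c, d)
            assert fisher_association(t).fisher_p == pytest.approx(
                fisher_association(t.transpose()).fisher_p
            )


class TestCovariateReport:
    def test_generator_calibration_recovery(self):
        """On a severity-linked synthetic cohort of 500, the score-age
        correlation comes back within +/-0.1 of the configured 0.7 target
        and the severity-linked group contrasts point the right way."""
        cohort = generate_cohort(GeneratorConfig(n_patients=500, seed=42))
        rep = score_vs_covariates_report(cohort)
        assert rep.correlations["age_years"].r == pytest.approx(0.7, abs=0.1)
        assert rep.correlations["chrispin_norman"].r > 0.6
        assert rep.correlations["fev1_pct_pred"].r < -0.4
        assert rep.correlations["lci"].r > 0.4
        cmp_path = rep.comparisons["cf_pathogens"]
        assert cmp_path.means[cmp_path.groups.index("True")] > cmp_path.means[
            cmp_path.groups.index("False")
        ]
        fungal = rep.comparisons["fungal_infection"]
        assert fungal.means[fungal.groups.index("True")] > fungal.means[
            fungal.groups.index("False")
        ]

    def test_missing_covariates_skipped_not_fatal(self):
        cohort = generate_cohort(
            GeneratorConfig(n_patients=40, seed=9, with_pft=False, with_radiograph=False)
        )
        rep = score_vs_covariates_report(cohort)
        assert "fev1_pct_pred" in rep.unavailable
        assert "chrispin_norman" in rep.unavailable
        assert "age_years" in rep.correlations

    def test_missing_counts_logged(self):
        cohort = generate_cohort(GeneratorConfig(n_patients=200, seed=1))
        rep = score_vs_covariates_report(cohort)
        assert rep.n_missing["lci"] > 0
        assert rep.n_missing["age_years"] == 0
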