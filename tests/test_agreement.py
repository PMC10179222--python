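"""Agreement statistics: kappa/PABAK, verbal bands, Lin's concordance,
slope CIs and the per-sign summary table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from cflus.agreement import (
    ContingencyTable2x2,
    altman_band,
    cohens_kappa,
    contingency_from_ratings,
    guilford_band,
    lins_ccc,
    pabak,
    pabak_adjusted_table,
    per_sign_agreement_summary,
    regression_slope_ci,
)

tables = st_h.tuples(
    st_h.integers(0, 40), st_h.integers(0, 40), st_h.integers(0, 40), st_h.integers(0, 40)
).filter(lambda t: sum(t) >= 1)


class TestContingency:
    @pytest.mark.parametrize(
        "r1,r2,cells",
        [
            ((1, 1, 0), (1, 1, 0), (2, 0, 0, 1)),
            ((1, 0), (0, 1), (0, 1, 1, 0)),
            ((1, 1, 1, 0), (1, 0, 1, 0), (2, 1, 0, 1)),
        ],
    )
    def test_cell_counts(self, r1, r2, cells):
        t = contingency_from_ratings(r1, r2)
        assert (t.a, t.b, t.c, t.d) == cells

    def test_rejects_length_mismatch_and_nonbinary(self):
        with pytest.raises(ValueError):
            contingency_from_ratings([1, 0], [1])
        with pytest.raises(ValueError):
            contingency_from_ratings([1, 2], [0, 1])


class TestKappa:
    def test_perfect_agreement(self):
        res = cohens_kappa(ContingencyTable2x2(10, 0, 0, 10))
        assert res.kappa == pytest.approx(1.0)
        assert res.po == 1.0

    def test_independence_gives_zero(self):
        res = cohens_kappa(ContingencyTable2x2(5, 5, 5, 5))
        assert res.kappa == pytest.approx(0.0)
        assert res.pe == pytest.approx(0.5)

    def test_hand_arithmetic_example(self):
        res = cohens_kappa(ContingencyTable2x2(20, 5, 10, 15))
        assert res.po == pytest.approx(0.70)
        assert res.pe == pytest.approx(0.50)
        assert res.kappa == pytest.approx(0.40)

    def test_degenerate_constant_raters_flagged(self):
        res = cohens_kappa(ContingencyTable2x2(10, 0, 0, 0))
        assert res.degenerate and res.kappa is None
        assert res.pabak == pytest.approx(1.0)

    def test_matches_statsmodels(self):
        """Cross-check the hand-rolled 2x2 kappa against statsmodels."""
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        rng = np.random.default_rng(7)
        for _ in range(30):
            a, b, c, d = rng.integers(1, 30, size=4)
            ours = cohens_kappa(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            theirs = sm_kappa([[a, b], [c, d]], return_results=True).kappa
            assert ours.kappa == pytest.approx(theirs, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(t=tables)
    def test_pabak_identity_and_rater_symmetry(self, t):
        """PABAK = 2*po - 1 = kappa of the margin-balanced adjusted table,
        and all statistics are invariant to swapping the raters."""
        table = ContingencyTable2x2(*t)
        p = pabak(table)
        assert p == pytest.approx(2 * (table.a + table.d) / table.n - 1)
        m, s, s2, m2 = pabak_adjusted_table(table)
        po = (m + m2) / table.n
        pe = ((m + s) * (m + s2) + (s2 + m2) * (s + m2)) / table.n**2
        if not math.isclose(pe, 1.0):
            assert p == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
        swapped = table.transpose()
        assert pabak(swapped) == pytest.approx(p)
        k1, k2 = cohens_kappa(table), cohens_kappa(swapped)
        if not k1.degenerate:
            assert k2.kappa == pytest.approx(k1.kappa, abs=1e-12)
        assert -1 <= p <= 1
        if not k1.degenerate:
            assert -1 - 1e-12 <= k1.kappa <= 1 + 1e-12
            if k1.kappa == pytest.approx(1.0):
                assert table.b == table.c == 0

    @pytest.mark.parametrize(
        "cells,expected",
        [((30, 5, 5, 10), 0.6), ((10, 0, 0, 10), 1.0), ((5, 5, 5, 5), 0.0)],
    )
    def test_pabak_examples(self, cells, expected):
        assert pabak(ContingencyTable2x2(*cells)) == pytest.approx(expected)


class TestBands:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (0.95, "very good"),
            (0.34, "fair"),
            (0.61, "good"),
            (0.60, "moderate"),  # boundary belongs to the band below
            (0.80, "good"),
            (0.10, "poor"),
            (-0.5, "poor"),
        ],
    )
    def test_altman(self, kappa, label):
        assert altman_band(kappa) == label

    @pytest.mark.parametrize(
        "r,label",
        [
            (0.95, "very high"),
            (0.90, "very high"),  # lower-inclusive convention
            (0.10, "negligible"),
            (-0.75, "high"),  # banded on |r|
            (0.4, "moderate"),
        ],
    )
    def test_guilford(self, r, label):
        assert guilford_band(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            altman_band(1.5)
        with pytest.raises(ValueError):
            guilford_band(-1.2)

    def test_lookup_is_total_on_a_grid(self):
        for v in np.linspace(-1, 1, 401):
            assert isinstance(altman_band(float(v)), str)
        for v in np.linspace(0, 1, 201):
            assert isinstance(guilford_band(float(v)), str)


class TestCCC:
    def test_identity_gives_one(self):
        assert lins_ccc([1, 2, 3, 4], [1, 2, 3, 4]).rho_c == pytest.approx(1.0)

    def test_location_shift_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = lins_ccc(x, x + 10)
        sx2 = np.var(x)
        assert res.rho_c == pytest.approx(2 * sx2 / (2 * sx2 + 100))

    def test_perfect_disagreement_pair(self):
        # direct evaluation of the defining formula at n=3
        x, y = np.array([0.0, 1.0, 2.0]), np.array([2.0, 1.0, 0.0])
        sxy = np.mean((x - x.mean()) * (y - y.mean()))
        expect = 2 * sxy / (np.var(x) + np.var(y) + (x.mean() - y.mean()) ** 2)
        assert lins_ccc(x, y).rho_c == pytest.approx(expect)
        assert expect == pytest.approx(-1.0)

    def test_ccc_bounded_by_pearson_with_equality_iff_matched_moments(self, rng):
        """|rho_c| <= |r|, equal iff the means and variances coincide; the
        estimate matches a brute-force moment computation to 1e-10."""
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x = rng.normal(rng.uniform(-3, 3), rng.uniform(0.5, 3), n)
            y = 0.7 * x + rng.normal(0, 1, n)
            res = lins_ccc(x, y)
            # brute-force moments
            sx2, sy2 = np.var(x), np.var(y)
            sxy = float(np.mean(x * y) - x.mean() * y.mean())
            brute = 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
            assert res.rho_c == pytest.approx(brute, abs=1e-10)
            assert abs(res.rho_c) <= abs(res.pearson_r) + 1e-12
        x = rng.normal(0, 1, 40)
        y = x.copy()
        assert lins_ccc(x, y).rho_c == pytest.approx(lins_ccc(x, y).pearson_r)

    def test_ci_brackets_estimate_and_degenerate_flagged(self, rng):
        x = rng.normal(10, 2, 50)
        y = x + rng.normal(0, 0.5, 50)
        res = lins_ccc(x, y)
        assert res.ci_low <= res.rho_c <= res.ci_high
        assert lins_ccc([1.0] * 5, [1.0] * 5).degenerate
        with pytest.raises(ValueError):
            lins_ccc([1, 2], [1, 2])


class TestSlopeCI:
    def test_exact_fit_collapses_ci(self):
        x = np.arange(5.0)
        res = regression_slope_ci(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.ci_low == pytest.approx(2.0)
        assert res.ci_high == pytest.approx(2.0)

    def test_perturbed_identity_contains_one(self):
        x = np.arange(10.0)
        y = x.copy()
        y[4] += 1.0
        res = regression_slope_ci(x, y)
        assert res.ci_low < 1.0 < res.ci_high

    def test_matches_matrix_computation(self, rng):
        x = rng.normal(0, 2, 40)
        y = 1.5 * x + rng.normal(0, 1, 40)
        res = regression_slope_ci(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            regression_slope_ci([1, 1, 1], [1, 2, 3])


class TestPerSignSummary:
    def test_identical_raters_all_perfect(self, rng):
        mat = rng.integers(0, 2, size=(30, 12))
        rows = per_sign_agreement_summary({"s1": (mat, mat.copy()), "s2": (mat, mat.copy())})
        for r in rows:
            assert r.kappa_mean == pytest.approx(1.0)
            assert r.band == "very good"

    def test_quarter_flip_rate_gives_pabak_near_half(self, rng):
        n = 4000
        r1 = rng.integers(0, 2, size=(n, 12))
        flips = rng.random((n, 12)) < 0.25
        r2 = np.where(flips, 1 - r1, r1)
        (row,) = per_sign_agreement_summary({"sign": (r1, r2)})
        assert row.kappa_mean == pytest.approx(0.5, abs=0.05)

    def test_all_degenerate_sign_reported_undefined(self):
        ones = np.ones((10, 3), dtype=int)
        (row,) = per_sign_agreement_summary({"sign": (ones, ones.copy())}, statistic="kappa")
        assert row.kappa_mean is None and row.band is None
        assert row.n_degenerate == 3

    def test_census_of_reference_mean_kappas(self):
        """The nine published per-sign mean agreement values band as
        very good x5 / good x1 / moderate x2 / fair x1."""
        means = [0.60, 0.34, 0.61, 0.95, 0.84, 0.57, 0.84, 0.94, 0.81]
        census = {}
        for m in means:
            census[altman_band(m)] = census.get(altman_band(m), 0) + 1
        assert census == {"very good": 5, "good": 1, "moderate": 2, "fair": 1}
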