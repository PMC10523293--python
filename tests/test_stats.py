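import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from housinglens.stats import (
    CapacityError,
    ChiSquaredResult,
    RatingMatrix,
    UndefinedKappaError,
    chi_squared,
    fisher_exact,
    fleiss_kappa,
    sample_adjudication,
    unanimity_rate,
)


def kappa_oracle(counts):
    """Independent hand-coded evaluation of the agreement formula."""
    counts = np.asarray(counts, dtype=float)
    n, k = counts.shape
    r = counts[0].sum()
    p_i = []
    for row in counts:
        p_i.append(sum(c * (c - 1) for c in row) / (r * (r - 1)))
    p_bar = sum(p_i) / n
    p_j = counts.sum(axis=0) / counts.sum()
    pe = sum(p**2 for p in p_j)
    return (p_bar - pe) / (1 - pe)


class TestRatingMatrix:
    def test_unequal_raters_rejected(self):
        with pytest.raises(ValueError):
            RatingMatrix(np.array([[3, 0], [2, 2]]))

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            RatingMatrix(np.array([[1, 0], [0, 1]]))

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            RatingMatrix(np.array([[3], [3]]))


class TestFleissKappa:
    def test_perfect_agreement(self):
        m = RatingMatrix(np.array([[3, 0], [0, 3], [3, 0]]))
        assert fleiss_kappa(m) == pytest.approx(1.0)

    def test_two_item_symmetry(self):
        m = RatingMatrix(np.array([[3, 0], [0, 3]]))
        assert fleiss_kappa(m) == pytest.approx(1.0)

    def test_undefined_when_single_category_used(self):
        m = RatingMatrix(np.array([[3, 0], [3, 0]]))
        with pytest.raises(UndefinedKappaError):
            fleiss_kappa(m)

    def test_random_matrices_match_oracle_and_statsmodels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(3)
        for _ in range(30):
            n, k, r = 10, int(rng.integers(2, 4)), 3
            counts = np.zeros((n, k), dtype=int)
            for i in range(n):
                votes = rng.integers(k, size=r)
                for v in votes:
                    counts[i, v] += 1
            m = RatingMatrix(counts)
            if counts.sum(axis=0).max() == counts.sum():
                continue
            got = fleiss_kappa(m)
            assert got == pytest.approx(kappa_oracle(counts))
            assert got == pytest.approx(sm_fleiss(counts, method="fleiss"))

    def test_range_and_permutation_invariance(self):
        rng = np.random.default_rng(9)
        counts = np.array([[2, 1], [3, 0], [1, 2], [0, 3], [2, 1]])
        m = RatingMatrix(counts)
        value = fleiss_kappa(m)
        assert -1.0 <= value <= 1.0
        perm = rng.permutation(len(counts))
        assert fleiss_kappa(RatingMatrix(counts[perm])) == pytest.approx(value)

    def test_convergence_to_planted_agreement(self):
        # planted model: with prob pi the item is clear (all raters agree on a
        # fair coin); otherwise raters vote independent fair coins.
        # Marginals are 1/2, so Pe = 1/2 and kappa = pi exactly.
        pi = 0.4
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = np.zeros((200, 2), dtype=int)
            for i in range(200):
                if rng.random() < pi:
                    counts[i, int(rng.random() < 0.5)] = 3
                else:
                    votes = (rng.random(3) < 0.5).astype(int)
                    counts[i, 0] = (votes == 0).sum()
                    counts[i, 1] = (votes == 1).sum()
            estimates.append(fleiss_kappa(RatingMatrix(counts)))
        assert abs(float(np.mean(estimates)) - pi) < 0.05


class TestUnanimity:
    def test_review_fixture(self):
        counts = np.array([[3, 0]] * 239 + [[2, 1]] * 61)
        assert round(100 * unanimity_rate(RatingMatrix(counts)), 1) == 79.7

    def test_all_unanimous(self):
        assert unanimity_rate(RatingMatrix(np.array([[3, 0], [0, 3]]))) == 1.0

    def test_against_row_scan_oracle(self):
        rng = np.random.default_rng(5)
        counts = np.zeros((50, 3), dtype=int)
        for i in range(50):
            for v in rng.integers(3, size=4):
                counts[i, v] += 1
        m = RatingMatrix(counts)
        expected = sum(1 for row in counts if max(row) == 4) / 50
        assert unanimity_rate(m) == pytest.approx(expected)


class TestChiSquared:
    def test_proportional_table_is_null(self):
        table = np.array([[10, 20], [20, 40]])
        res = chi_squared(table)
        assert res.statistic == pytest.approx(0.0)
        assert np.allclose(res.adjusted_residuals, 0.0)

    def test_2x2_against_hand_computed_oracle(self):
        table = np.array([[10, 20], [20, 10]])
        res = chi_squared(table)
        # independent oracle: scipy for the statistic, direct formula for
        # the adjusted residuals
        stat, p, df, expected = sp_stats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)
        assert res.df == df
        n = table.sum()
        rows = table.sum(axis=1)
        cols = table.sum(axis=0)
        for i in range(2):
            for j in range(2):
                denom = np.sqrt(
                    expected[i, j] * (1 - rows[i] / n) * (1 - cols[j] / n)
                )
                assert res.adjusted_residuals[i, j] == pytest.approx(
                    (table[i, j] - expected[i, j]) / denom
                )

    def test_residual_signs_flip_under_row_swap(self):
        table = np.array([[10, 20], [20, 10]])
        res = chi_squared(table)
        flipped = chi_squared(table[::-1])
        assert np.allclose(flipped.adjusted_residuals, res.adjusted_residuals[::-1])
        # in a 2x2, swapping the rows negates each original row's residuals
        assert np.allclose(flipped.adjusted_residuals[0], -res.adjusted_residuals[0])

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            chi_squared(np.array([[0, 0], [1, 2]]))


class TestFisherExact:
    def test_2x2_diagonal_matches_closed_form(self):
        table = np.array([[5, 0], [0, 5]])
        p = fisher_exact(table)
        # closed form: only the two diagonal tables are as extreme
        expected = 2.0 * sp_stats.hypergeom.pmf(5, 10, 5, 5)
        assert p == pytest.approx(expected)
        assert p == pytest.approx(sp_stats.fisher_exact(table)[1])

    def test_identical_rows_p_one(self):
        assert fisher_exact(np.array([[4, 6], [4, 6]])) == pytest.approx(1.0)

    def test_2x2_grid_matches_scipy(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum() == 0:
                continue
            ours = fisher_exact(table)
            assert ours == pytest.approx(sp_stats.fisher_exact(table)[1], rel=1e-9)

    def test_monte_carlo_consistent_with_exact_on_2x3(self):
        table = np.array([[8, 2, 4], [3, 7, 5]])
        exact = fisher_exact(table)
        reps = 20000
        mc = fisher_exact(table, monte_carlo=True, n_replicates=reps, seed=10)
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(mc - exact) <= 3 * se + 1e-4

    def test_capacity_guard(self):
        table = np.array([[50, 60, 70], [80, 40, 30], [20, 90, 10]])
        with pytest.raises(CapacityError):
            fisher_exact(table, guard=100)

    def test_ordering_extreme_vs_balanced(self):
        extreme = np.array([[9, 1], [1, 9]])
        balanced = np.array([[5, 5], [5, 5]])
        assert fisher_exact(extreme) < fisher_exact(balanced)
        assert chi_squared(extreme).p_value < chi_squared(balanced).p_value


class TestSampleAdjudication:
    def make_mentions(self, n_per_method=150):
        rows = []
        idx = 0
        for method in ("keyword", "ner", "shelter_name"):
            for _ in range(n_per_method):
                rows.append(
                    {
                        "note_id": f"N{idx}",
                        "method": method,
                        "surface": "homeless",
                        "start": 0,
                        "end": 8,
                    }
                )
                idx += 1
        return pd.DataFrame(rows)

    def test_three_strata_quota(self):
        mentions = self.make_mentions()
        sheet = sample_adjudication(mentions, {}, 100, seed=1)
        assert len(sheet) == 300
        assert sheet["method"].value_counts().to_dict() == {
            "keyword": 100, "ner": 100, "shelter_name": 100
        }

    def test_zero_quota_empty_sheet(self):
        sheet = sample_adjudication(self.make_mentions(), {}, 0, seed=1)
        assert len(sheet) == 0

    def test_determinism(self):
        mentions = self.make_mentions()
        a = sample_adjudication(mentions, {}, 50, seed=7)
        b = sample_adjudication(mentions, {}, 50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_small_stratum_sampled_exhaustively(self):
        mentions = self.make_mentions(n_per_method=30)
        sheet = sample_adjudication(mentions, {}, 100, seed=2)
        assert sheet["method"].value_counts().to_dict() == {
            "keyword": 30, "ner": 30, "shelter_name": 30
        }

    def test_rating_columns_blank(self):
        sheet = sample_adjudication(self.make_mentions(), {}, 10, seed=3)
        assert {"rater_1", "rater_2", "rater_3"} <= set(sheet.columns)
        assert (sheet["rater_1"] == "").all()
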