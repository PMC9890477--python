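"""Unit and oracle tests for the shared nonparametric statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from amygdecode.stats import (
    auc,
    friedman_chi2_batch_k3,
    friedman_permutation_p,
    friedman_statistic,
    reflect_auc,
    spearman,
    wilcoxon_signed_rank,
)


def wilcoxon_exact_oracle(a, b):
    """Brute-force two-sided p: enumerate all 2^n sign assignments of the
    rank magnitudes and double the smaller tail of W+."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [np.sum(ranks[np.array(signs, dtype=bool)]) for signs in itertools.product([0, 1], repeat=n)]
    )
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonSignedRank:
    def test_all_zero_differences(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == 1.0

    def test_uniform_shift_exact_p(self):
        # all 6 differences negative: the most extreme of 2^6 assignments
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7])
        assert res.pvalue == pytest.approx(2 / 64)

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_matches_signflip_enumeration(self, n, rng):
        for _ in range(20):
            a = rng.integers(0, 6, size=n).astype(float)
            b = rng.integers(0, 6, size=n).astype(float)
            if np.all(a == b):
                continue
            ours = wilcoxon_signed_rank(a, b).pvalue
            oracle = wilcoxon_exact_oracle(a, b)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_large_sample_matches_scipy_normal_approximation(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60) + 0.3
        ours = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, correction=True, method="approx")
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


class TestFriedman:
    def test_identical_columns_give_chi2_zero(self):
        res = friedman_statistic([[2.0, 2.0, 2.0]] * 5)
        assert res.chi2 == 0.0 and res.pvalue == 1.0

    def test_hand_computed_concordant_table(self):
        # 4 blocks all ranked 1<2<3: rank sums (4, 8, 12) -> chi2 = 8, df = 2
        res = friedman_statistic([[1, 2, 3]] * 4)
        assert res.chi2 == pytest.approx(8.0)
        assert res.df == 2

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(25):
            table = rng.integers(0, 5, size=(8, 3)).astype(float)
            ref_cols = [table[:, j] for j in range(3)]
            try:
                ref = sps.friedmanchisquare(*ref_cols)
            except (ValueError, ZeroDivisionError):
                continue
            ours = friedman_statistic(table)
            if np.isnan(ref.statistic):
                continue
            assert ours.chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_batch_matches_scalar(self, rng):
        tables = rng.integers(0, 4, size=(30, 6, 3)).astype(float)
        batch = friedman_chi2_batch_k3(tables)
        for i in range(30):
            assert batch[i] == pytest.approx(friedman_statistic(tables[i]).chi2, abs=1e-10)

    def test_permutation_p_matches_full_enumeration(self, rng):
        # exact null: all 6^b within-block orderings, b <= 6 blocks
        for _ in range(4):
            table = rng.integers(0, 4, size=(4, 3)).astype(float)
            obs = friedman_statistic(table).chi2
            perms3 = list(itertools.permutations(range(3)))
            chis = []
            for combo in itertools.product(perms3, repeat=table.shape[0]):
                permuted = np.array([table[i, list(p)] for i, p in enumerate(combo)])
                chis.append(friedman_statistic(permuted).chi2)
            chis = np.array(chis)
            p_exact = np.mean(chis >= obs - 1e-12)
            p_mc = friedman_permutation_p(table, n_permutations=4000, seed=9)
            se = np.sqrt(p_exact * (1 - p_exact) / 4000)
            assert abs(p_mc - p_exact) < max(4 * se, 0.01)


class TestAuc:
    def test_identical_distributions(self):
        assert auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_full_separation(self):
        assert auc([5, 6, 7], [1, 2, 3]) == 1.0

    def test_matches_pairwise_enumeration(self, rng):
        for _ in range(30):
            a = rng.integers(0, 5, size=rng.integers(1, 9))
            b = rng.integers(0, 5, size=rng.integers(1, 9))
            wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert auc(a, b) == pytest.approx(wins / (len(a) * len(b)))

    @pytest.mark.parametrize(
        "raw,expected", [(0.45, 0.55), (0.5, 0.5), (0.93, 0.93), (0.0, 1.0)]
    )
    def test_reflection(self, raw, expected):
        assert reflect_auc(raw) == pytest.approx(expected)


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rs == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exact_p_matches_permutation_enumeration(self, n, rng):
        for _ in range(5):
            x = rng.normal(size=n)
            y = rng.integers(0, 3, size=n).astype(float)
            if np.ptp(y) == 0:
                continue
            res = spearman(x, y)
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            rxc, ryc = rx - rx.mean(), ry - ry.mean()
            denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
            rs_all = np.array(
                [ryc[list(p)] @ rxc / denom for p in itertools.permutations(range(n))]
            )
            p_exact = np.mean(np.abs(rs_all) >= abs(res.rs) - 1e-12)
            assert res.pvalue == pytest.approx(p_exact, abs=1e-12)

    def test_rank_invariance_under_duplication(self):
        x, y = [1, 2, 3, 5, 8], [2, 1, 5, 4, 9]
        assert spearman(x * 2, y * 2).rs == pytest.approx(spearman(x, y).rs)
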