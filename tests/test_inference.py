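"""Statistical battery against independent enumeration oracles, and the
threshold-determination rule."""

import itertools
import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import conchvision as cv
from conchvision.exceptions import DomainError, ValidationError
from conchvision.trials import ResponseTable

# ---------------------------------------------------------------------------
# Oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------


def wilson_oracle(k, n, conf=0.95):
    """Closed-form Wilson score bounds from the quadratic in p."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf / 2.0)
    phat = k / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


def fisher_two_sided_oracle(k1, n1, k2, n2):
    """Sum of hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed table."""
    K, N = k1 + k2, n1 + n2

    def pr(x):
        return comb(n1, x) * comb(n2, K - x) / comb(N, K)

    p_obs = pr(k1)
    lo, hi = max(0, K - n2), min(n1, K)
    return sum(pr(x) for x in range(lo, hi + 1) if pr(x) <= p_obs * (1 + 1e-12))


def spearman_exact_oracle(x, y):
    """Two-sided permutation p for Spearman rho by brute-force enumeration."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_exact_oracle(d):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    total_rank = n * (n + 1) / 2
    dev_obs = abs(v_obs - total_rank / 2)
    hits = 0
    for signs in itertools.product([0, 1], repeat=n):
        v = sum(r for r, s in zip(ranks, signs) if s)
        if abs(v - total_rank / 2) >= dev_obs - 1e-12:
            hits += 1
    return hits / 2**n


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


class TestWilsonInterval:
    def test_zero_responders_of_forty(self):
        est = cv.wilson_interval(0, 40)
        assert est.lower == 0.0
        assert est.upper == pytest.approx(0.088, abs=0.001)

    def test_all_responders_upper_is_one(self):
        est = cv.wilson_interval(40, 40)
        assert est.upper == pytest.approx(1.0)
        assert est.lower == pytest.approx(1 - 0.088, abs=0.001)

    def test_half_responders_symmetric_about_point(self):
        est = cv.wilson_interval(20, 40)
        assert est.point == 0.5
        assert est.upper - est.point == pytest.approx(est.point - est.lower)

    @given(st.integers(0, 60), st.integers(1, 60))
    def test_matches_closed_form(self, k, n):
        k = min(k, n)
        est = cv.wilson_interval(k, n)
        lo, hi = wilson_oracle(k, n)
        assert est.lower == pytest.approx(lo, abs=1e-9)
        assert est.upper == pytest.approx(hi, abs=1e-9)
        assert 0.0 <= est.lower <= est.point <= est.upper <= 1.0

    def test_width_shrinks_with_n(self):
        wide = cv.wilson_interval(5, 10)
        narrow = cv.wilson_interval(50, 100)
        assert (narrow.upper - narrow.lower) < (wide.upper - wide.lower)

    def test_zero_trials_rejected(self):
        with pytest.raises(DomainError):
            cv.wilson_interval(0, 0)


class TestSpearman:
    def test_perfect_correlations(self):
        x = np.arange(5.0)
        assert cv.spearman(x, x).rho == pytest.approx(1.0)
        assert cv.spearman(x, -x).rho == pytest.approx(-1.0)

    def test_exact_permutation_p_matches_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.1, 0.5, 0.3, 0.9, 0.8])
        res = cv.spearman(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(spearman_exact_oracle(x, y), abs=1e-12)

    def test_exact_permutation_with_ties(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0.1, 0.1, 0.3, 0.3, 0.9, 0.8])
        res = cv.spearman(x, y)
        assert res.p_value == pytest.approx(spearman_exact_oracle(x, y), abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            res = cv.spearman([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert math.isnan(res.rho)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(3)
        x = np.arange(20.0)
        y = x + rng.normal(0, 5, 20)
        res = cv.spearman(x, y)
        assert res.method == "t-approx"
        assert 0 < res.p_value < 1


class TestFisherExact:
    def test_identical_columns_p_one(self):
        assert cv.fisher_exact(8, 40, 8, 40).p_value == pytest.approx(1.0)

    def test_two_sided_matches_enumeration(self):
        assert cv.fisher_exact(8, 40, 0, 40).p_value == pytest.approx(
            fisher_two_sided_oracle(8, 40, 0, 40), abs=1e-12
        )

    def test_one_sided_tail_product(self):
        # P(all 8 responders fall in the responding group) given margins:
        # prod_{i=0..7} (40-i)/(80-i)
        expected = math.prod((40 - i) / (80 - i) for i in range(8))
        assert cv.fisher_exact(8, 40, 0, 40, alternative="greater").p_value == pytest.approx(
            expected, rel=1e-9
        )

    @given(st.integers(1, 12), st.integers(1, 12), st.data())
    def test_agrees_with_enumeration_on_small_margins(self, n1, n2, data):
        k1 = data.draw(st.integers(0, n1))
        k2 = data.draw(st.integers(0, n2))
        p = cv.fisher_exact(k1, n1, k2, n2).p_value
        assert p == pytest.approx(fisher_two_sided_oracle(k1, n1, k2, n2), abs=1e-9)

    def test_empty_margins(self):
        assert cv.fisher_exact(0, 0, 0, 0).p_value == 1.0


class TestBonferroni:
    def test_adjustment_and_clipping(self):
        adj = cv.bonferroni([0.01, 0.5], m=9)
        assert adj[0] == pytest.approx(0.09)
        assert adj[1] == 1.0
        assert cv.bonferroni([0.2], m=1)[0] == pytest.approx(0.2)

    def test_m_smaller_than_family_rejected(self):
        with pytest.raises(DomainError):
            cv.bonferroni([0.1, 0.2, 0.3], m=2)


class TestWilcoxon:
    def test_identical_pairs(self):
        res = cv.wilcoxon_signed_rank_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_exact_p_matches_sign_enumeration(self):
        # tie-free |differences| so the exact method applies
        a = np.array([1.0, 2.5, 3.0, 4.8, 5.0, 6.5])
        b = np.array([1.2, 2.0, 3.6, 4.0, 5.45, 6.1])
        res = cv.wilcoxon_signed_rank_paired(a, b)
        assert res.p_value == pytest.approx(wilcoxon_exact_oracle(a - b), abs=1e-12)

    def test_swapping_arguments_reflects_statistic(self):
        a = np.array([1.0, 2.5, 3.0, 4.8, 5.0, 6.5])
        b = np.array([1.2, 2.0, 3.6, 4.0, 5.45, 6.1])
        v_ab = cv.wilcoxon_signed_rank_paired(a, b).statistic
        v_ba = cv.wilcoxon_signed_rank_paired(b, a).statistic
        n = 6
        assert v_ab + v_ba == n * (n + 1) / 2


def make_table(ks, ns, levels, control=(0, 38), experiment="resolution"):
    rows = [{"level": lv, "k": k, "n": n, "is_control": False} for lv, k, n in zip(levels, ks, ns)]
    rows.append({"level": 0.0, "k": control[0], "n": control[1], "is_control": True})
    return ResponseTable(experiment, pd.DataFrame(rows))


class TestDetermineThreshold:
    LEVELS = (0.3, 0.4, 0.53, 0.8, 1.1, 1.6, 2.2, 3.2)

    def significant_from(self, break_level):
        ks = [34 if lv >= break_level else 1 for lv in self.LEVELS]
        return make_table(ks, [38] * 8, self.LEVELS)

    def test_break_at_053_gives_alpha_min_106(self):
        res = cv.determine_threshold(self.significant_from(0.53))
        assert res.threshold_level == pytest.approx(0.53)
        assert res.alpha_min_deg == pytest.approx(1.06)

    def test_no_significant_level(self):
        table = make_table([1] * 8, [38] * 8, self.LEVELS)
        res = cv.determine_threshold(table)
        assert res.threshold_level is None and res.alpha_min_deg is None

    @pytest.mark.parametrize("m", [8, 9, 16])
    def test_threshold_stable_under_family_size(self, m):
        res = cv.determine_threshold(self.significant_from(0.8), m=m)
        assert res.threshold_level == pytest.approx(0.8)

    def test_adjusted_p_matches_direct_fisher(self):
        table = self.significant_from(0.53)
        res = cv.determine_threshold(table)
        row = res.per_level[res.per_level["level"] == 0.53].iloc[0]
        direct = fisher_two_sided_oracle(34, 38, 0, 38)
        assert row["p_value"] == pytest.approx(direct, abs=1e-12)
        assert row["p_adjusted"] == pytest.approx(min(1.0, 8 * direct), abs=1e-12)

    def test_monotone_adding_responders_above_never_raises_threshold(self):
        base = cv.determine_threshold(self.significant_from(0.8)).threshold_level
        ks = [34 if lv >= 0.8 else 1 for lv in self.LEVELS]
        ks[-1] = 38  # extra responders at the top level
        boosted = cv.determine_threshold(make_table(ks, [38] * 8, self.LEVELS)).threshold_level
        assert boosted <= base

    def test_missing_control_rejected(self):
        rows = pd.DataFrame(
            [{"level": 0.53, "k": 30, "n": 38, "is_control": False}]
        )
        with pytest.raises(ValidationError, match="control"):
            cv.determine_threshold(ResponseTable("resolution", rows))


class TestModelResults:
    def test_fit_reports_threshold_intervals_and_summary(self):
        table = make_table(
            [1, 2, 34, 36, 37, 36, 38, 38], [38] * 8, TestDetermineThreshold.LEVELS
        )
        model = cv.DetectionThresholdModel.from_response_table(table)
        res = model.fit()
        assert res.threshold_level == pytest.approx(0.53)
        assert res.alpha_min_deg == pytest.approx(1.06)
        # Wilson bounds present and ordered for every level
        df = res.per_level
        assert ((df["wilson_lower"] <= df["p_hat"]) & (df["p_hat"] <= df["wilson_upper"])).all()
        assert res.level_correlation.rho > 0.9
        text = res.summary()
        assert "1.06" in text and "Threshold level" in text

    def test_from_dataframe_constructor(self):
        df = make_table([1, 34], [38, 38], (0.4, 0.53)).levels
        res = cv.DetectionThresholdModel.from_dataframe(df, "resolution").fit()
        assert res.threshold_level == pytest.approx(0.53)
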