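"""ROC cut-offs, stratification, Fisher, Kaplan-Meier, log-rank, paired t."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from melpipe import (
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
    paired_pre_post,
    pairwise_logrank,
    progression_free_at,
    roc_cutoff,
    stratify,
)


def brute_force_fisher_p(a, b, c, d):
    """Enumerate all tables with the observed margins; sum probabilities of
    those no more probable than the observed table."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = stats.hypergeom.pmf(x, n, row1, col1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def brute_force_youden(marker, outcome):
    best_j, best_cut = -np.inf, None
    for cut in sorted(set(marker)):
        pred = np.asarray(marker) >= cut
        sens = (pred & outcome).sum() / outcome.sum()
        spec = (~pred & ~outcome).sum() / (~outcome).sum()
        j = sens + spec - 1
        if j > best_j:  # ties keep the smaller cutoff
            best_j, best_cut = j, cut
    return best_cut, best_j


class TestRocCutoff:
    def test_perfect_separation(self):
        marker = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        outcome = np.array([False, False, False, True, True, True])
        res = roc_cutoff(marker, outcome)
        assert res.youden_j == pytest.approx(1.0)
        assert 3.0 < res.cutoff <= 10.0

    def test_matches_exhaustive_search_on_toys(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            marker = rng.normal(size=20).round(2)
            outcome = rng.random(20) < 0.5
            if outcome.all() or not outcome.any():
                continue
            res = roc_cutoff(marker, outcome)
            cut, j = brute_force_youden(marker, outcome)
            assert res.cutoff == pytest.approx(cut)
            assert res.youden_j == pytest.approx(j)

    def test_single_class_outcome_is_error(self):
        with pytest.raises(ValueError, match="single class"):
            roc_cutoff(np.array([1.0, 2.0]), np.array([True, True]))

    def test_monotone_transform_maps_cutoff(self):
        rng = np.random.default_rng(1)
        marker = rng.uniform(0, 100, 40)
        outcome = marker + rng.normal(0, 20, 40) > 50
        if outcome.all() or not outcome.any():
            pytest.skip("degenerate draw")
        res = roc_cutoff(marker, outcome)
        res_t = roc_cutoff(np.log1p(marker), outcome)
        assert res_t.cutoff == pytest.approx(np.log1p(res.cutoff))
        assert res_t.youden_j == pytest.approx(res.youden_j)

    def test_null_marker_keeps_j_small_on_average(self):
        rng = np.random.default_rng(2)
        js = []
        for _ in range(50):
            marker = rng.normal(size=500)
            outcome = rng.random(500) < 0.5
            js.append(roc_cutoff(marker, outcome).youden_j)
        assert 0 < np.mean(js) < 0.15  # optimism of the maximized J only


class TestProgressionFreeAt:
    def test_exclude_policy_drops_early_censored(self):
        times = np.array([2.0, 8.0, 3.0, 7.0])
        events = np.array([True, True, False, False])
        outcome, valid = progression_free_at(times, events, horizon=6.0)
        assert valid.tolist() == [True, True, False, True]
        assert outcome[valid].tolist() == [False, True, True]

    def test_non_progressor_policy_keeps_everyone(self):
        times = np.array([2.0, 3.0])
        events = np.array([True, False])
        outcome, valid = progression_free_at(
            times, events, horizon=6.0, censored_policy="non_progressor"
        )
        assert valid.all()
        assert outcome.tolist() == [False, True]


class TestStratify:
    def _cohort(self, cd8, cd155):
        return pd.DataFrame({"cd8_count": cd8, "cd155_score": cd155})

    def test_boundary_cd8_at_cutoff_is_high(self):
        out = stratify(self._cohort([82.8], [0]), 82.8)
        assert out.loc[0, "group"] == "CD8hi/CD155lo"

    def test_cd155_score_one_is_low(self):
        out = stratify(self._cohort([10.0], [1]), 82.8)
        assert out.loc[0, "group"] == "CD8lo/CD155lo"

    def test_cd155_score_two_is_high(self):
        out = stratify(self._cohort([100.0], [2]), 82.8)
        assert out.loc[0, "group"] == "CD8hi/CD155hi"

    def test_groups_partition_cohort(self):
        rng = np.random.default_rng(0)
        cohort = self._cohort(rng.uniform(0, 200, 50), rng.integers(0, 4, 50))
        out = stratify(cohort, 82.8)
        assert len(out) == 50
        assert out["group"].value_counts().sum() == 50

    def test_missing_marker_excluded(self):
        out = stratify(self._cohort([50.0, np.nan], [1, 2]), 82.8)
        assert len(out) == 1


class TestFisherExact:
    def test_reported_cohort_composition_comparison(self):
        """CD8-high/CD155-low membership by melanoma type: 19/63 vs 22/81."""
        odds, p = fisher_exact_2x2(19, 44, 22, 59)
        assert odds == pytest.approx(19 * 59 / (44 * 22))
        assert p == pytest.approx(0.7132, abs=5e-4)

    def test_matches_enumeration_oracle_on_small_margins(self):
        rng = np.random.default_rng(3)
        tables = [(5, 0, 0, 5), (1, 2, 3, 4), (0, 7, 7, 0), (4, 4, 4, 4)]
        tables += [tuple(rng.integers(0, 11, 4)) for _ in range(30)]
        for a, b, c, d in tables:
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(brute_force_fisher_p(a, b, c, d), abs=1e-9)

    def test_identical_rows_give_p_one(self):
        _, p = fisher_exact_2x2(6, 4, 6, 4)
        assert p == pytest.approx(1.0)

    def test_invariant_under_transposition_and_swaps(self):
        a, b, c, d = 3, 9, 7, 2
        _, p0 = fisher_exact_2x2(a, b, c, d)
        for table in [(a, c, b, d), (c, d, a, b), (b, a, d, c)]:
            assert fisher_exact_2x2(*table)[1] == pytest.approx(p0)

    def test_zero_margin_convention(self):
        _, p = fisher_exact_2x2(0, 0, 5, 7)
        assert p == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([False] * 3))
        assert (km["survival"] == 1.0).all()

    def test_four_distinct_events(self):
        km = km_estimate(np.array([1.0, 2.0, 3.0, 4.0]), np.array([True] * 4))
        assert km["survival"].tolist() == pytest.approx([1.0, 0.75, 0.5, 0.25, 0.0])

    def test_interleaved_censoring_matches_hand_computation(self):
        # events at 1, 3, 5; censored at 2 and 4:
        # S(1)=4/5, S(3)=4/5*2/3=8/15, S(5)=0
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([True, False, True, False, True])
        km = km_estimate(times, events).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(0.8)
        assert km.loc[3.0] == pytest.approx(8 / 15)
        assert km.loc[5.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, 40).round(2)
        km = km_estimate(times, np.ones(40, dtype=bool))
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((times > t).mean())

    def test_survival_non_increasing_from_one(self):
        rng = np.random.default_rng(5)
        km = km_estimate(rng.exponential(5, 50), rng.random(50) < 0.7)
        assert km["survival"].iloc[0] == 1.0
        assert (np.diff(km["survival"]) <= 1e-12).all()


class TestLogrank:
    def test_group_against_itself_is_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([True, True, False, True])
        chi2, df, p = logrank_test([(t, e), (t, e)])
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_o_minus_e_on_toy(self):
        """Two-group statistic equals the squared standardized O-E sum."""
        t1, e1 = np.array([1.0, 3.0, 5.0]), np.array([True, True, True])
        t2, e2 = np.array([2.0, 4.0, 6.0]), np.array([True, True, True])
        chi2, _, _ = logrank_test([(t1, e1), (t2, e2)])
        times = np.concatenate([t1, t2])
        events = np.concatenate([e1, e2])
        group = np.array([0, 0, 0, 1, 1, 1])
        o_minus_e, var = 0.0, 0.0
        for t in sorted(times[events]):
            at_risk = times >= t
            n, n1 = at_risk.sum(), (at_risk & (group == 0)).sum()
            d = ((times == t) & events).sum()
            d1 = ((times == t) & events & (group == 0)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert chi2 == pytest.approx(o_minus_e**2 / var)

    def test_three_group_df(self):
        rng = np.random.default_rng(6)
        groups = [
            (rng.exponential(5, 30), np.ones(30, dtype=bool)) for _ in range(3)
        ]
        _, df, _ = logrank_test(groups)
        assert df == 2

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            logrank_test([(np.array([1.0]), np.array([True])), (np.array([]), np.array([]))])

    def test_power_against_hazard_ratio_three(self):
        rng = np.random.default_rng(7)
        hits = 0
        reps = 30
        for _ in range(reps):
            t1 = rng.exponential(10, 200)
            t2 = rng.exponential(10 / 3, 200)
            e = np.ones(200, dtype=bool)
            hits += logrank_test([(t1, e), (t2, e)])[2] < 0.05
        assert hits / reps > 0.9

    def test_pairwise_bonferroni(self):
        rng = np.random.default_rng(8)
        groups = {
            name: (rng.exponential(scale, 40), np.ones(40, dtype=bool))
            for name, scale in [("a", 10), ("b", 10), ("c", 2)]
        }
        out = pairwise_logrank(groups)
        assert len(out) == 3
        np.testing.assert_allclose(
            out["p_adjusted"], np.minimum(out["p_raw"] * 3, 1.0)
        )


class TestPairedPrePost:
    def test_no_change_gives_p_one(self):
        pre = np.array([1.0, 2.0, 3.0])
        mean_change, p = paired_pre_post(pre, pre)
        assert mean_change == 0.0 and p == 1.0

    def test_matches_textbook_formula(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        post = np.array([2.0, 2.0, 4.0, 4.0, 7.0])
        mean_change, p = paired_pre_post(pre, post)
        diff = post - pre
        t = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        expected_p = 2 * stats.t.sf(abs(t), df=len(diff) - 1)
        assert mean_change == pytest.approx(0.8)
        assert p == pytest.approx(expected_p)

    def test_constant_shift_detected_reliably(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(40):
            pre = rng.normal(10, 2, 25)
            post = pre + 1.0 + rng.normal(0, 0.8, 25)
            hits += paired_pre_post(pre, post)[1] < 0.05
        assert hits / 40 >= 0.95

    def test_degenerate_nonzero_shift_warns(self):
        pre = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero variance"):
            mean_change, p = paired_pre_post(pre, pre + 2.0)
        assert mean_change == 2.0 and p == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            paired_pre_post(np.array([1.0, 2.0]), np.array([1.0]))
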