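"""Time-to-onset computation, ECDF, rank tests and BH adjustment."""

import datetime as dt
import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from fqvigil.report_model import DrugMention, ReactionMention
from fqvigil.synthetic_reports import SimConfig, simulate
from fqvigil.tto_analysis import (
    Dropped,
    TTOSample,
    bh_adjust,
    compute_tto,
    compute_tto_samples,
    ecdf,
    kruskal_wallis,
    wilcoxon_rank_sum,
)


def tto_case(case_factory, start, event, pt="anxiety"):
    return case_factory(
        drugs=[
            DrugMention("ciprofloxacin", "suspect",
                        frozenset({"J01MA02"}), start)
        ],
        reactions=[ReactionMention(pt, event)],
    )


class TestComputeTTO:
    def test_two_day_interval(self, case_factory, dictionary):
        s = compute_tto(
            tto_case(case_factory, dt.date(2020, 1, 1), dt.date(2020, 1, 3)),
            "psychiatric disorders", dictionary,
        )
        assert isinstance(s, TTOSample) and s.tto_days == 2

    def test_same_day_onset_is_day_zero(self, case_factory, dictionary):
        s = compute_tto(
            tto_case(case_factory, dt.date(2020, 1, 1), dt.date(2020, 1, 1)),
            "psychiatric disorders", dictionary,
        )
        assert isinstance(s, TTOSample) and s.tto_days == 0

    def test_event_before_start_dropped_inconsistent(
        self, case_factory, dictionary
    ):
        out = compute_tto(
            tto_case(case_factory, dt.date(2020, 1, 2), dt.date(2020, 1, 1)),
            "psychiatric disorders", dictionary,
        )
        assert isinstance(out, Dropped) and out.reason == "inconsistent"

    def test_missing_date_dropped_with_reason(self, case_factory, dictionary):
        out = compute_tto(
            tto_case(case_factory, None, dt.date(2020, 1, 1)),
            "psychiatric disorders", dictionary,
        )
        assert isinstance(out, Dropped) and out.reason == "missing"

    def test_non_qualifying_soc_dropped(self, case_factory, dictionary):
        out = compute_tto(
            tto_case(case_factory, dt.date(2020, 1, 1), dt.date(2020, 1, 3),
                     pt="tendonitis"),
            "psychiatric disorders", dictionary,
        )
        assert isinstance(out, Dropped)
        assert out.reason == "no_qualifying_event"

    def test_earliest_event_and_start_used(self, case_factory, dictionary):
        case = case_factory(
            drugs=[
                DrugMention("ciprofloxacin", "suspect",
                            frozenset({"J01MA02"}), dt.date(2020, 1, 5)),
                DrugMention("levofloxacin", "suspect",
                            frozenset({"J01MA12"}), dt.date(2020, 1, 1)),
            ],
            reactions=[
                ReactionMention("anxiety", dt.date(2020, 1, 10)),
                ReactionMention("insomnia", dt.date(2020, 1, 4)),
            ],
        )
        s = compute_tto(case, "psychiatric disorders", dictionary)
        assert s.tto_days == 3  # Jan 4 − Jan 1


class TestECDF:
    def test_hand_counted_step_points(self):
        curve = ecdf([0, 1, 1, 7])
        assert dict(curve["points"])[1] == 0.75
        assert curve["median"] == 1
        assert curve["points"][-1][1] == 1.0

    def test_all_within_seven_days(self):
        assert ecdf([0, 1, 2, 3])["fraction_within_7_days"] == 1.0

    def test_monotone_right_continuous_terminal_one(self):
        rng = np.random.default_rng(0)
        curve = ecdf(rng.integers(0, 50, size=200).tolist())
        fs = [f for _, f in curve["points"]]
        assert all(x < y for x, y in zip(fs, fs[1:]))
        assert fs[-1] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])

    def test_simulated_lognormal_median_near_two_days(self, dictionary):
        config = SimConfig(
            n_cases=10000, duplicate_fraction=0.0, psychotropic_rate=0.0,
            missing_rates={}, seed=19,
        )
        cases, _ = simulate(config)
        samples, drops = compute_tto_samples(
            cases, "psychiatric disorders", dictionary
        )
        assert len(samples) > 200
        curve = ecdf(samples)
        assert 1 <= curve["median"] <= 3
        assert curve["fraction_within_7_days"] > 0.7


def wilcoxon_enumeration_oracle(x, y):
    """Two-sided p by brute enumeration of all rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2
    w_obs = ranks[:n1].sum()
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        count += abs(w - mu) >= abs(w_obs - mu) - 1e-9
        total += 1
    return count / total


class TestWilcoxon:
    def test_identical_multisets_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.method == "wilcoxon_exact"
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_three_vs_three(self):
        # most extreme of the C(6,3)=20 rank assignments, both tails
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(2 / 20)

    def test_exact_matches_enumeration_for_small_groups(self):
        rng = np.random.default_rng(5)
        for n1, n2 in [(3, 4), (5, 5), (4, 8), (8, 8)]:
            x = rng.integers(0, 6, size=n1)  # small support forces ties
            y = rng.integers(0, 6, size=n2)
            res = wilcoxon_rank_sum(x, y)
            assert res.p_value == pytest.approx(
                wilcoxon_enumeration_oracle(x, y), abs=1e-12
            ), (x, y)

    def test_asymptotic_close_to_exact_at_n15(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1, 15)
        exact = wilcoxon_rank_sum(x, y).p_value  # n=15 uses the exact branch
        approx = float(
            stats.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        )
        assert approx == pytest.approx(exact, abs=0.005)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])


class TestKruskalWallis:
    def test_identical_groups_h_zero_p_one(self):
        omnibus, _ = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert omnibus.statistic == 0.0 and omnibus.p_value == 1.0

    def test_matches_permutation_oracle_on_tiny_groups(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        omnibus, _ = kruskal_wallis(groups)
        # permutation distribution of H over random relabelings
        pooled = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        rng = np.random.default_rng(0)
        count = 0
        n_perm = 20000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            h = stats.kruskal(perm[:2], perm[2:4], perm[4:])[0]
            count += h >= omnibus.statistic - 1e-9
        p_perm = count / n_perm
        # chi-square p is asymptotic; require agreement within MC error + bias
        assert omnibus.p_value == pytest.approx(p_perm, abs=0.05)

    def test_two_group_kw_close_to_wilcoxon_asymptotic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 100)
        y = rng.normal(0.3, 1, 100)
        omnibus, _ = kruskal_wallis([x, y])
        w = float(
            stats.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic",
                               use_continuity=False).pvalue
        )
        assert omnibus.p_value == pytest.approx(w, abs=0.01)

    def test_planted_shift_detected_with_high_power(self):
        rng = np.random.default_rng(11)
        detected = 0
        n_rep = 50
        for _ in range(n_rep):
            base = rng.lognormal(np.log(2), 1, size=(2, 200)).round()
            shifted = rng.lognormal(np.log(3), 1, size=200).round()
            omnibus, _ = kruskal_wallis([base[0], base[1], shifted])
            detected += omnibus.p_value < 0.05
        assert detected >= 0.9 * n_rep

    def test_pairwise_family_is_bh_adjusted(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 30) for m in (0, 0, 1)]
        _, pairwise = kruskal_wallis(groups)
        raws = [v["p"] for v in pairwise.values()]
        adjusted = [v["p_adjusted"] for v in pairwise.values()]
        assert adjusted == bh_adjust(raws)
        assert all(a >= r for a, r in zip(adjusted, raws))


class TestBHAdjust:
    def test_hand_applied_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_elementwise_dominance_and_order_preservation(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        adj = bh_adjust(p)
        assert all(a >= r for a, r in zip(adj, p))
        order_p = np.argsort(p)
        assert all(
            adj[order_p[i]] <= adj[order_p[i + 1]] + 1e-12
            for i in range(len(p) - 1)
        )

    def test_fixed_points_of_the_step_up_rule(self):
        # constant vectors are BH fixed points: p(m)·m/m = p(m) dominates
        for vec in ([0.04, 0.04, 0.04, 0.04], [1.0, 1.0], [0.3]):
            assert bh_adjust(vec) == pytest.approx(vec)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        p = rng.random(20)
        perm = rng.permutation(20)
        assert np.asarray(bh_adjust(p))[perm] == pytest.approx(
            bh_adjust(p[perm])
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
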