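"""Trial statistics: response summaries, CA19-9, KM, log-rank, Simon."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from tmeniche.clinical import (
    ca199_decline,
    evaluate_two_stage,
    km_estimate,
    logrank_test,
    simon_two_stage,
    summarize_response,
)


class TestResponseSummary:
    def test_trial_counts_reproduce_printed_rates(self):
        """1 CR + 23 PR + 41 SD + 7 PD: ORR 33.3%, DCR 90.3%."""
        responses = ["CR"] + ["PR"] * 23 + ["SD"] * 41 + ["PD"] * 7
        s = summarize_response(responses)
        assert s.n == 72
        assert s.orr_percent == 33.3
        assert s.dcr_percent == 90.3

    def test_all_progressive_disease(self):
        s = summarize_response(["PD"] * 5)
        assert s.orr_percent == 0.0 and s.dcr_percent == 0.0

    def test_random_table_matches_independent_tally(self):
        rng = np.random.default_rng(0)
        values = list(rng.choice(["CR", "PR", "SD", "PD"], size=200))
        s = summarize_response(values)
        # independent recount
        tally = {lvl: sum(v == lvl for v in values) for lvl in set(values)}
        orr = round(100 * (tally.get("CR", 0) + tally.get("PR", 0)) / 200, 1)
        dcr = round(100 * (200 - tally.get("PD", 0)) / 200, 1)
        assert s.orr_percent == orr and s.dcr_percent == dcr

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ValueError):
            summarize_response([])
        with pytest.raises(ValueError, match="unknown"):
            summarize_response(["CR", "XX"])


class TestCA199:
    def test_toy_decline_classification(self):
        df = pd.DataFrame({"ca199_baseline": [100.0], "ca199_nadir": [75.0]})
        out = ca199_decline(df)
        assert out.counts[20.0] == 1 and out.counts[90.0] == 0

    def test_increase_meets_no_threshold(self):
        df = pd.DataFrame({"ca199_baseline": [100.0], "ca199_nadir": [140.0]})
        out = ca199_decline(df)
        assert out.counts[20.0] == 0

    def test_non_evaluable_excluded(self):
        df = pd.DataFrame(
            {"ca199_baseline": [100.0, np.nan, 0.0],
             "ca199_nadir": [10.0, 5.0, 0.0]}
        )
        out = ca199_decline(df)
        assert out.n_evaluable == 1 and out.n_excluded == 2

    def test_negative_concentration_rejected(self):
        df = pd.DataFrame({"ca199_baseline": [-1.0], "ca199_nadir": [0.0]})
        with pytest.raises(ValueError, match="negative"):
            ca199_decline(df)


class TestKaplanMeier:
    def test_hand_computed_product_limit_table(self):
        """8 subjects, 2 censored: estimates equal the hand calculation."""
        times = [1, 2, 2, 3, 4, 5, 6, 7]
        events = [1, 1, 1, 1, 0, 1, 0, 1]
        curve = km_estimate(times, events, landmarks=(3.5,))
        s = pd.Series(curve.survival, index=curve.timeline)
        assert s.loc[1.0] == pytest.approx(7 / 8)
        assert s.loc[2.0] == pytest.approx(7 / 8 * 5 / 7)   # = 0.625
        assert s.loc[3.0] == pytest.approx(0.625 * 4 / 5)   # = 0.5
        assert s.loc[5.0] == pytest.approx(0.5 * 2 / 3)
        assert s.loc[7.0] == pytest.approx(0.0)
        assert curve.median == 3.0  # first time with S <= 0.5
        assert curve.landmark_survival[3.5] == pytest.approx(0.5)

    def test_no_censoring_equals_empirical_survivor(self):
        times = np.arange(1, 11, dtype=float)
        curve = km_estimate(times, np.ones(10, bool))
        s = pd.Series(curve.survival, index=curve.timeline)
        for t in times:
            assert s.loc[t] == pytest.approx((times > t).mean())
        assert curve.median == 5.0

    def test_all_censored_curve_flat_median_unreached(self):
        curve = km_estimate([3.0, 6.0, 9.0], [False, False, False])
        assert (curve.survival == 1.0).all()
        assert np.isinf(curve.median)

    def test_estimate_monotone_nonincreasing_from_one(self):
        rng = np.random.default_rng(1)
        curve = km_estimate(rng.exponential(5, 50),
                            rng.random(50) < 0.7)
        assert curve.survival[0] <= 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()


def hand_logrank(times_a, events_a, times_b, events_b):
    """Independent observed-minus-expected log-rank oracle."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b]).astype(bool)
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    O = E = V = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (group == 0)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_oracle_on_toy_data(self):
        ta, ea = np.array([1.0, 3.0, 5.0, 7.0]), np.array([1, 1, 0, 1])
        tb, eb = np.array([2.0, 4.0, 6.0, 8.0]), np.array([1, 0, 1, 1])
        stat, _ = logrank_test(ta, ea, tb, eb)
        assert stat == pytest.approx(hand_logrank(ta, ea, tb, eb), rel=1e-6)

    def test_no_events_returns_null_result(self):
        stat, p = logrank_test([1.0, 2.0], [False, False],
                               [3.0], [False])
        assert (stat, p) == (0.0, 1.0)

    def test_null_rejection_rate_calibrated(self):
        """Equal exponential hazards: ~5% rejections at alpha 0.05."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.exponential(10, 30)
            b = rng.exponential(10, 30)
            c = rng.uniform(5, 25, 60)
            ta, tb = np.minimum(a, c[:30]), np.minimum(b, c[30:])
            ea, eb = a <= c[:30], b <= c[30:]
            _, p = logrank_test(ta, ea, tb, eb)
            rejections += p < 0.05
        assert 0.035 <= rejections / n_rep <= 0.065


class TestSimon:
    def test_stage1_boundary_certain_stop_at_zero_rate(self):
        pet, rej, en = evaluate_two_stage(r1=5, n1=17, r=20, n=49, p=0.0)
        assert pet == 1.0 and rej == 0.0 and en == 17.0

    def test_certain_continuation_at_rate_one(self):
        pet, rej, en = evaluate_two_stage(r1=5, n1=17, r=20, n=49, p=1.0)
        assert pet == 0.0 and rej == 1.0 and en == 49.0

    def test_reject_probability_monotone_in_p(self):
        probs = [evaluate_two_stage(5, 14, 20, 44, p)[1]
                 for p in np.linspace(0.05, 0.95, 10)]
        assert (np.diff(probs) >= -1e-12).all()

    def test_matches_exhaustive_enumeration_oracle(self):
        """Exact OCs agree with direct summation over all outcomes."""
        design = (5, 14, 20, 44)
        for p in (0.35, 0.55):
            r1, n1, r, n = design
            total = 0.0
            for x1 in range(n1 + 1):
                if x1 <= r1:
                    continue
                for x2 in range(n - n1 + 1):
                    if x1 + x2 > r:
                        total += (binom.pmf(x1, n1, p)
                                  * binom.pmf(x2, n - n1, p))
            _, rej, _ = evaluate_two_stage(*design, p)
            assert rej == pytest.approx(total, abs=1e-12)

    def test_monte_carlo_agreement(self):
        """10^6-rep simulation within 3 Monte-Carlo SEs of exact values."""
        r1, n1, r, n = 5, 14, 20, 44
        rng = np.random.default_rng(0)
        reps = 1_000_000
        for p in (0.35, 0.55):
            x1 = rng.binomial(n1, p, reps)
            x2 = rng.binomial(n - n1, p, reps)
            go = x1 > r1
            rej_mc = (go & (x1 + x2 > r)).mean()
            _, rej, _ = evaluate_two_stage(r1, n1, r, n, p)
            se = np.sqrt(rej * (1 - rej) / reps)
            assert abs(rej_mc - rej) < 3 * se
            pet_mc = (~go).mean()
            pet = evaluate_two_stage(r1, n1, r, n, p)[0]
            se_pet = np.sqrt(pet * (1 - pet) / reps) + 1e-12
            assert abs(pet_mc - pet) < 4 * se_pet

    def test_search_satisfies_constraints_and_ordering(self):
        opt = simon_two_stage(0.35, 0.55, 0.05, 0.20, "optimal", n_max=60)
        mm = simon_two_stage(0.35, 0.55, 0.05, 0.20, "minimax", n_max=60)
        for d in (opt, mm):
            assert d.attained_alpha <= 0.05 + 1e-12
            assert d.attained_power >= 0.80 - 1e-12
            assert d.n1 < d.n
        assert opt.en0 <= mm.en0 + 1e-9
        assert mm.n <= opt.n

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simon_two_stage(0.55, 0.35)
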