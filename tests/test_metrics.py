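"""Model-free estimators: hit rates, thresholds, false-alarm formulas,
reaction times, and the bootstrap machinery."""

import numpy as np
import pandas as pd
import pytest

from clickchange import metrics as met


def _frame(rows):
    base = dict(
        trial_id=0, cue="increase", direction="increase", delta_hz=50.0,
        change_time_s=3.0, max_time_s=3.8, response_time_s=np.nan,
        reported_dir=None, outcome="miss",
    )
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d.update(r)
        d["trial_id"] = i
        out.append(d)
    return pd.DataFrame(out)


class TestHitRate:
    def test_three_hits_one_miss(self):
        rows = [{"outcome": "hit"}] * 3 + [{"outcome": "miss"}]
        r, ci, k, n = met.hit_rate(_frame(rows), "informed_increase", 50.0)
        assert (r, k, n) == (0.75, 3, 4)

    def test_false_alarms_leave_the_denominator(self):
        rows = [{"outcome": "hit"}] * 3 + [{"outcome": "false_alarm",
                                            "response_time_s": 2.0,
                                            "reported_dir": "increase"}]
        r, ci, k, n = met.hit_rate(_frame(rows), "informed_increase", 50.0)
        assert (r, n) == (1.0, 3)
        assert ci[1] == pytest.approx(1.0)

    def test_no_qualifying_trials_raises(self):
        rows = [{"outcome": "hit"}]
        with pytest.raises(met.EstimatorError):
            met.hit_rate(_frame(rows), "informed_decrease", 50.0)


class TestThreshold:
    @staticmethod
    def _psych_frame(deltas, rates, n_each=40, cue="increase"):
        rows = []
        for d, p in zip(deltas, rates):
            k = int(round(p * n_each))
            rows += [{"delta_hz": d, "outcome": "hit", "cue": cue,
                      "direction": cue, "response_time_s": 3.3,
                      "reported_dir": cue}] * k
            rows += [{"delta_hz": d, "outcome": "miss", "cue": cue,
                      "direction": cue}] * (n_each - k)
        return _frame(rows)

    def test_symmetric_logistic_midpoint(self):
        trials = self._psych_frame([10.0, 30.0, 50.0], [0.1, 0.5, 0.9])
        s = met.fit_threshold(trials, "informed_increase", n_boot=20)
        assert s.threshold == pytest.approx(30.0, abs=0.2)
        assert not s.extrapolated

    def test_threshold_scales_with_deltas(self):
        a = self._psych_frame([10.0, 30.0, 50.0], [0.1, 0.5, 0.9])
        b = self._psych_frame([20.0, 60.0, 100.0], [0.1, 0.5, 0.9])
        ta = met.fit_threshold(a, "informed_increase", n_boot=5).threshold
        tb = met.fit_threshold(b, "informed_increase", n_boot=5).threshold
        assert tb == pytest.approx(2 * ta, rel=0.02)

    def test_generative_recovery_of_midpoint(self):
        rng = np.random.default_rng(3)
        deltas = [10.0, 20.0, 30.0, 40.0, 50.0]
        true_mid, width = 35.0, 8.0
        rates = []
        n = 500
        for d in deltas:
            p = 1.0 / (1.0 + np.exp(-(d - true_mid) / width))
            rates.append(rng.binomial(n, p) / n)
        trials = self._psych_frame(deltas, rates, n_each=n)
        s = met.fit_threshold(trials, "informed_increase", n_boot=200,
                              rng=np.random.default_rng(5))
        assert s.threshold_ci[0] <= true_mid <= s.threshold_ci[1]
        assert s.threshold == pytest.approx(true_mid, abs=3.0)

    def test_decreasing_rates_rejected(self):
        trials = self._psych_frame([10.0, 30.0, 50.0], [0.9, 0.5, 0.1])
        with pytest.raises(met.EstimatorError):
            met.fit_threshold(trials, "informed_increase", n_boot=5)

    def test_decrease_condition_threshold_is_negative(self):
        trials = self._psych_frame([10.0, 30.0, 50.0], [0.1, 0.5, 0.9],
                                   cue="decrease")
        trials["delta_hz"] = -trials["delta_hz"]
        trials["direction"] = "decrease"
        s = met.fit_threshold(trials, "informed_decrease", n_boot=5)
        assert s.threshold == pytest.approx(-30.0, abs=0.2)


class TestFalseAlarmRates:
    @staticmethod
    def _fa_frame(n_uninf=100, fa_inc=10, fa_dec=5):
        rows = []
        for _ in range(fa_inc):
            rows.append({"cue": "either", "outcome": "false_alarm",
                         "reported_dir": "increase", "response_time_s": 2.0})
        for _ in range(fa_dec):
            rows.append({"cue": "either", "outcome": "false_alarm",
                         "reported_dir": "decrease", "response_time_s": 2.0})
        for _ in range(n_uninf - fa_inc - fa_dec):
            rows.append({"cue": "either", "outcome": "miss"})
        # informed trials so the informed estimators are defined
        rows += [{"cue": "increase", "outcome": "miss"}] * 10
        rows += [{"cue": "decrease", "outcome": "miss"}] * 10
        return _frame(rows)

    def test_uninformed_formula_discounts_other_direction(self):
        out = met.false_alarm_rates(self._fa_frame())
        assert out["uninformed_increase"].rate == pytest.approx(10 / 95)
        assert out["uninformed_decrease"].rate == pytest.approx(5 / 90)

    def test_zero_false_alarms_gives_zero(self):
        out = met.false_alarm_rates(self._fa_frame(fa_inc=0, fa_dec=0))
        assert out["uninformed_increase"].rate == 0.0
        assert out["informed_increase"].rate == 0.0

    def test_informed_rate_keeps_opposite_cue_trials_in_denominator(self):
        rows = []
        for _ in range(5):
            rows.append({"cue": "increase", "outcome": "false_alarm",
                         "reported_dir": "increase", "response_time_s": 2.0})
        for _ in range(2):
            rows.append({"cue": "increase", "outcome": "opposite_cue_excluded",
                         "reported_dir": "decrease", "response_time_s": 2.0})
        rows += [{"cue": "increase", "outcome": "miss"}] * 43
        rows += [{"cue": "decrease", "outcome": "miss"}] * 10
        rows += [{"cue": "either", "outcome": "miss"}] * 10
        out = met.false_alarm_rates(_frame(rows))
        assert out["informed_increase"].rate == pytest.approx(5 / 50)

    def test_estimators_agree_when_other_direction_has_no_fas(self):
        out = met.false_alarm_rates(self._fa_frame(fa_inc=8, fa_dec=0))
        # with no opposite false alarms the uninformed denominator is the
        # plain trial count, the same rule the informed estimator uses
        assert out["uninformed_increase"].rate == pytest.approx(8 / 100)


class TestReactionTimes:
    def test_mean_of_two_hits(self):
        rows = [
            {"outcome": "hit", "response_time_s": 3.4},
            {"outcome": "hit", "response_time_s": 3.6},
        ]
        m, ci, n = met.reaction_times(_frame(rows), "informed_increase", n_boot=50)
        assert m == pytest.approx(0.5)

    def test_single_hit_collapses_interval(self):
        rows = [{"outcome": "hit", "response_time_s": 3.4}]
        m, ci, n = met.reaction_times(_frame(rows), "informed_increase", n_boot=50)
        assert ci[0] == ci[1] == pytest.approx(m)

    def test_no_hits_raises(self):
        with pytest.raises(met.EstimatorError):
            met.reaction_times(_frame([{"outcome": "miss"}]),
                               "informed_increase", n_boot=10)

    def test_bootstrap_interval_covers_true_mean(self):
        # nominal 5th/95th percentile interval: coverage near 90%
        rng = np.random.default_rng(21)
        true_mean, cover, reps = 0.5, 0, 100
        for _ in range(reps):
            rts = rng.gamma(4.0, true_mean / 4.0, size=200)
            rows = [{"outcome": "hit", "response_time_s": 3.0 + r} for r in rts]
            m, ci, _ = met.reaction_times(
                _frame(rows), "informed_increase", n_boot=300,
                rng=np.random.default_rng(int(rng.integers(2**31))),
            )
            cover += ci[0] <= true_mean <= ci[1]
        assert 0.80 <= cover / reps <= 0.97


class TestBootstrapTest:
    def test_identical_groups_give_large_p(self, rng):
        a = rng.normal(size=80)
        assert met.bootstrap_test(a, a.copy(), rng=rng) > 0.9

    def test_large_shift_gives_small_p(self, rng):
        a = rng.normal(size=100)
        b = rng.normal(size=100) + 10 * a.std()
        assert met.bootstrap_test(a, b, rng=rng) <= 0.001

    def test_constant_pooled_data_returns_one(self):
        assert met.bootstrap_test(np.ones(5), np.ones(7)) == 1.0

    def test_one_sided_detects_direction(self, rng):
        a = rng.normal(1.0, 1.0, size=150)
        b = rng.normal(0.0, 1.0, size=150)
        assert met.bootstrap_test(a, b, sided="one", rng=rng) < 0.01

    def test_p_never_exactly_zero(self, rng):
        a = rng.normal(0, 0.1, size=50)
        b = a + 100.0
        p = met.bootstrap_test(a, b, n_boot=100, rng=rng)
        assert p >= 1.0 / 101
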