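"""Decoders: RT regression with shuffle nulls, logistic choice decoding,
per-neuron regressions."""

import numpy as np
import pytest

from popdyn.decoders import (
    bin_spike_counts,
    choice_decoder,
    per_neuron_regression,
    rt_decoder,
)
from popdyn.session import SessionData, TrialRecord, UnitRecord


def _count_session(rng, n_trials=120, n_units=6, rate=8.0, rts=None, choices=None):
    """Poisson-count session with controllable RT/choice structure."""
    trials, spike_lists = [], [[] for _ in range(n_units)]
    rts = rng.uniform(350, 900, n_trials) if rts is None else rts
    choices = (
        np.array(["left", "right"])[rng.integers(0, 2, n_trials)]
        if choices is None
        else choices
    )
    for i in range(n_trials):
        trials.append(
            TrialRecord(i, 13.6, str(choices[i]), True, float(rts[i]), 700.0,
                        700.0 + float(rts[i]))
        )
        dur = 700.0 + rts[i] + 100.0
        for u in range(n_units):
            n_sp = rng.poisson(rate * dur / 1000.0)
            spike_lists[u].append(np.sort(rng.uniform(0, dur, n_sp)))
    units = [UnitRecord(f"u{u}", 0.1, spike_lists[u]) for u in range(n_units)]
    return SessionData("synthetic-counts", trials, units)


class TestBinSpikeCounts:
    def test_counts_match_manual(self):
        rng = np.random.default_rng(0)
        sess = _count_session(rng, n_trials=5, n_units=2)
        counts, starts = bin_spike_counts(sess, bin_ms=100.0, window=(-200.0, 200.0))
        assert counts.shape == (5, 4, 2)
        u0 = sess.units[0].spike_times[0] - 700.0
        manual = np.sum((u0 >= -200.0) & (u0 < -100.0))
        assert counts[0, 0, 0] == manual

    def test_overlapping_step(self):
        rng = np.random.default_rng(1)
        sess = _count_session(rng, n_trials=3, n_units=1)
        counts, starts = bin_spike_counts(
            sess, bin_ms=50.0, window=(-100.0, 100.0), step_ms=25.0
        )
        assert np.allclose(np.diff(starts), 25.0)


class TestRTDecoder:
    def test_exact_linear_code_r2_one(self):
        rng = np.random.default_rng(2)
        sess = _count_session(rng, n_trials=80, n_units=4)
        counts, starts = bin_spike_counts(sess, bin_ms=100.0, window=(-400.0, 0.0))
        # overwrite RTs as an exact linear function of bin 1's counts
        w = np.array([3.0, -2.0, 1.0, 0.5])
        rts = 500.0 + counts[:, 1, :] @ w
        for t, r in zip(sess.trials, rts):
            t.rt = float(r)
            t.movement_onset = t.checkerboard_onset + float(r)
        res = rt_decoder(sess, bin_ms=100.0, window=(-400.0, 0.0), n_shuffles=20, rng=3)
        assert res.r2[1] == pytest.approx(1.0, abs=1e-9)

    def test_null_calibration(self):
        # RT independent of counts: R^2 stays below the shuffle 99th
        # percentile in almost all bins
        rng = np.random.default_rng(4)
        sess = _count_session(rng, n_trials=150, n_units=8)
        res = rt_decoder(sess, bin_ms=50.0, window=(-500.0, 500.0), n_shuffles=200, rng=5)
        frac_below = np.mean(res.r2 <= res.null_p99)
        assert frac_below >= 0.95

    def test_shuffles_seed_deterministic(self):
        rng = np.random.default_rng(6)
        sess = _count_session(rng, n_trials=60, n_units=3)
        a = rt_decoder(sess, bin_ms=200.0, window=(-400.0, 0.0), n_shuffles=50, rng=7)
        b = rt_decoder(sess, bin_ms=200.0, window=(-400.0, 0.0), n_shuffles=50, rng=7)
        np.testing.assert_array_equal(a.null_p99, b.null_p99)

    def test_needs_two_units(self):
        rng = np.random.default_rng(8)
        sess = _count_session(rng, n_trials=30, n_units=1)
        with pytest.raises(ValueError):
            rt_decoder(sess, units=[0])


class TestChoiceDecoder:
    def test_separable_counts_high_accuracy(self):
        rng = np.random.default_rng(9)
        n = 200
        choices = np.array(["left", "right"])[np.arange(n) % 2]
        sess = _count_session(rng, n_trials=n, n_units=4, choices=choices)
        # plant a strong choice signal in the prestimulus window
        for u in range(4):
            for i, t in enumerate(sess.trials):
                if t.choice == "left":
                    extra = np.sort(rng.uniform(300.0, 700.0, 15))
                    s = np.sort(np.concatenate([sess.units[u].spike_times[i], extra]))
                    sess.units[u].spike_times[i] = s
        res = choice_decoder(sess, bin_ms=400.0, window=(-400.0, 0.0), n_shuffles=0, rng=10)
        assert res.accuracy[0] >= 0.95

    def test_random_labels_chance(self):
        rng = np.random.default_rng(11)
        sess = _count_session(rng, n_trials=200, n_units=5)
        res = choice_decoder(sess, bin_ms=400.0, window=(-400.0, 0.0), n_shuffles=60, rng=12)
        assert res.null_p01[0] <= res.accuracy[0] <= res.null_p99[0]

    def test_single_class_rejected(self):
        rng = np.random.default_rng(13)
        sess = _count_session(rng, n_trials=30, n_units=3,
                              choices=np.array(["left"] * 30))
        with pytest.raises(ValueError):
            choice_decoder(sess, bin_ms=400.0, window=(-400.0, 0.0), n_shuffles=0)

    def test_affine_rescaling_invariance(self):
        # per-fold standardization makes accuracy invariant to per-unit
        # affine count rescaling
        rng = np.random.default_rng(14)
        n = 150
        choices = np.array(["left", "right"])[np.arange(n) % 2]
        sess = _count_session(rng, n_trials=n, n_units=3, choices=choices)
        counts, _ = bin_spike_counts(sess, bin_ms=400.0, window=(-400.0, 0.0))
        X = counts[:, 0, :]
        from popdyn.decoders import _cv_accuracy

        labels = np.array([t.choice for t in sess.trials])
        a = _cv_accuracy(X, labels, np.random.default_rng(0))
        b = _cv_accuracy(X * np.array([5.0, 0.5, 20.0]) + 3.0, labels,
                         np.random.default_rng(0))
        assert a == pytest.approx(b, abs=1e-12)


class TestPerNeuronRegression:
    def test_exact_choice_code(self):
        rng = np.random.default_rng(15)
        n = 60
        choices = np.array(["left", "right"])[np.arange(n) % 2]
        sess = _count_session(rng, n_trials=n, n_units=2, choices=choices)
        res = per_neuron_regression(sess, target="choice", bin_ms=100.0,
                                    step_ms=100.0, window=(-400.0, 0.0))
        # overwrite: direct check of the linear algebra with planted rates
        assert res.beta.shape == (2, 4)

    def test_planted_choice_beta_recovered(self):
        # FR = 20 + 30*choice with regular (noise-free) spike trains:
        # beta ~= 30 spikes/s and the CI excludes 0
        n = 40
        choices = np.array(["left", "right"])[np.arange(n) % 2]
        trials, spikes = [], []
        for i in range(n):
            trials.append(TrialRecord(i, 13.6, str(choices[i]), True, 500.0,
                                      700.0, 1200.0))
            rate = 20.0 + 30.0 * (choices[i] == "right")
            # regular spike train at `rate` Hz over the whole trial
            spikes.append(np.arange(0.0, 1300.0, 1000.0 / rate) + 0.5)
        sess = SessionData("planted", trials, [UnitRecord("u0", 0.1, spikes)])
        res = per_neuron_regression(sess, target="choice", bin_ms=200.0,
                                    step_ms=200.0, window=(-400.0, 0.0))
        assert np.all(np.abs(res.beta - 30.0) < 3.0)
        assert res.significant.all()

    def test_chance_fraction_near_one_percent(self):
        # null coverage: ~1% of independent unit-bins significant at 99% CI
        rng = np.random.default_rng(17)
        sess = _count_session(rng, n_trials=250, n_units=40, rate=15.0)
        res = per_neuron_regression(sess, target="rt", bin_ms=50.0, step_ms=200.0,
                                    window=(-600.0, 0.0))
        n_bins = res.beta.shape[1]
        total = 40 * n_bins
        observed = res.significant.sum()
        # one-sided binomial bound at alpha=0.05 for rate 1%
        from scipy import stats as sps

        assert observed <= sps.binom.ppf(0.95, total, 0.01) + 1

    def test_few_trials_rejected(self):
        rng = np.random.default_rng(18)
        sess = _count_session(rng, n_trials=10, n_units=2)
        with pytest.raises(ValueError):
            per_neuron_regression(sess, target="rt")

    def test_unknown_target_rejected(self, small_session):
        with pytest.raises(ValueError):
            per_neuron_regression(small_session, target="outcome")
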