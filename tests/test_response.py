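"""Confidence bands, CI-divergence runs, hinge onsets and rank tests."""

import numpy as np
import pytest

import driftpulse as dp
from driftpulse.kinematics import AlignedEnsemble
from driftpulse.response import (CIBand, average_with_ci, band_nonoverlap,
                                 compare_conditions, detect_divergence,
                                 peak_in_window, piecewise_linear_onset)


def _ensemble_from_matrix(vals, t=None):
    """Wrap an (n_trials, n_samples) array as a velocity-channel ensemble."""
    n, m = vals.shape
    t = np.arange(m) if t is None else t
    z = np.zeros_like(vals)
    return AlignedEnsemble(t=t, x=z, y=vals, vx=z, vy=vals,
                           valid=np.ones_like(vals, dtype=bool),
                           conditions=np.array(["c"] * n),
                           trial_ids=np.arange(n))


def _band(t, mean, half):
    mean = np.asarray(mean, dtype=float)
    half = np.broadcast_to(np.asarray(half, dtype=float), mean.shape)
    return CIBand(t=np.asarray(t), mean=mean, lo=mean - half, hi=mean + half,
                  n=np.full(mean.shape, 100), defined=np.ones_like(mean, bool))


class TestAverageWithCI:
    def test_identical_trials_zero_width(self):
        ens = _ensemble_from_matrix(np.tile(np.sin(np.arange(50) / 5), (12, 1)))
        band = average_with_ci(ens, "vy")
        assert np.allclose(band.lo, band.hi)
        assert np.allclose(band.mean, ens.vy[0])

    def test_fewer_than_ten_trials_fully_flagged(self, rng):
        ens = _ensemble_from_matrix(rng.normal(size=(9, 40)))
        band = average_with_ci(ens, "vy")
        assert not band.defined.any()
        assert np.all(np.isnan(band.lo))

    def test_gaussian_halfwidth_matches_closed_form(self, rng):
        sigma = 2.0
        ens = _ensemble_from_matrix(rng.normal(0, sigma, size=(400, 30)))
        band = average_with_ci(ens, "vy")
        half = (band.hi - band.lo) / 2
        expect = 1.966 * sigma / np.sqrt(400)     # t(0.975, 399) ~ 1.966
        assert np.mean(half) == pytest.approx(expect, rel=0.1)

    def test_bootstrap_agrees_with_t(self, rng):
        ens = _ensemble_from_matrix(rng.normal(1.0, 1.0, size=(200, 20)))
        bt = average_with_ci(ens, "vy", method="t")
        bb = average_with_ci(ens, "vy", method="bootstrap",
                             rng=np.random.default_rng(5))
        np.testing.assert_allclose(bb.lo, bt.lo, atol=0.05)
        np.testing.assert_allclose(bb.hi, bt.hi, atol=0.05)

    def test_all_invalid_column_flagged_not_error(self, rng):
        ens = _ensemble_from_matrix(rng.normal(size=(20, 30)))
        ens.valid[:, 10] = False
        band = average_with_ci(ens, "vy")
        assert not band.defined[10] and band.defined[11]


class TestDivergence:
    t = np.arange(0, 300)

    def test_equal_bands_no_runs(self):
        a = _band(self.t, np.zeros(300), 1.0)
        runs = detect_divergence(a, a)
        assert runs.runs == [] and runs.significant == []

    def test_constructed_disjoint_interval_recovered(self):
        mean_b = np.zeros(300)
        mean_a = np.where((self.t >= 80) & (self.t <= 140), 5.0, 0.0)
        runs = detect_divergence(_band(self.t, mean_a, 1.0),
                                 _band(self.t, mean_b, 1.0))
        assert len(runs.significant) == 1
        r = runs.significant[0]
        assert r.start == 80 and r.length == 61    # inclusive 80..140

    def test_short_nonoverlap_reported_but_not_significant(self):
        mean_a = np.where((self.t >= 100) & (self.t < 115), 5.0, 0.0)
        runs = detect_divergence(_band(self.t, mean_a, 1.0),
                                 _band(self.t, np.zeros(300), 1.0))
        assert runs.significant == []
        assert len(runs.runs) == 1 and runs.runs[0].length == 15

    def test_matches_bruteforce_scan(self, rng):
        """Run detection must equal a per-ms overlap scan + run-length
        encoding on arbitrary band pairs."""
        for _ in range(20):
            a = _band(self.t, rng.normal(size=300), rng.uniform(0.5, 1.5, 300))
            b = _band(self.t, rng.normal(size=300), rng.uniform(0.5, 1.5, 300))
            mask = np.array([(a.lo[i] > b.hi[i]) or (b.lo[i] > a.hi[i])
                             for i in range(300)])
            # brute-force run-length encoding
            expected = []
            start = None
            for i in range(301):
                on = i < 300 and mask[i]
                if on and start is None:
                    start = i
                elif not on and start is not None:
                    expected.append((start, i - start))
                    start = None
            got = [(int(r.start), int(r.length))
                   for r in detect_divergence(a, b, min_run=1).runs]
            assert got == expected

    def test_mismatched_axes_rejected(self):
        a = _band(np.arange(100), np.zeros(100), 1.0)
        b = _band(np.arange(50), np.zeros(50), 1.0)
        with pytest.raises(ValueError):
            detect_divergence(a, b)

    def test_t_min_restricts_onset_search(self):
        mean_a = np.where(self.t < 40, 5.0, 0.0)
        runs = detect_divergence(_band(self.t, mean_a, 1.0),
                                 _band(self.t, np.zeros(300), 1.0), t_min=50.0)
        assert runs.significant == []


class TestPeakInWindow:
    def test_monotone_trace_peaks_at_boundary(self):
        t = np.arange(0, 200)
        val, lat = peak_in_window(t, t * 0.1, (50, 140))
        assert lat == 140 and val == pytest.approx(14.0)

    def test_all_zero_tie_breaks_earliest(self):
        t = np.arange(0, 200)
        val, lat = peak_in_window(t, np.zeros(200), (50, 140))
        assert val == 0.0 and lat == 50

    def test_undefined_window_raises(self):
        t = np.arange(0, 200)
        with pytest.raises(ValueError, match="undefined"):
            peak_in_window(t, np.full(200, np.nan), (50, 140))


class TestPiecewiseLinearOnset:
    def test_exact_hinge_recovered(self):
        t = np.arange(-200, 400, dtype=float)
        y = np.where(t > 100, (t - 100) * 0.03, 0.0) + 0.001 * t
        assert piecewise_linear_onset(t, y, search=(0, 300)) == 100

    def test_noisy_hinge_within_5ms(self, rng):
        t = np.arange(-200, 400, dtype=float)
        y = np.where(t > 120, (t - 120) * 0.05, 0.0) + rng.normal(0, 0.1, t.size)
        got = piecewise_linear_onset(t, y, search=(0, 300))
        assert abs(got - 120) <= 5

    def test_flat_trace_returns_null(self):
        t = np.arange(-100, 300, dtype=float)
        assert piecewise_linear_onset(t, np.zeros(t.size)) is None


class TestCompareConditions:
    def test_identical_groups_not_significant(self, rng):
        g = rng.normal(size=200)
        rep = compare_conditions({"a": g, "b": g.copy()})
        assert rep.test == "ranksum"
        assert rep.p_value > 0.9

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_conditions({"a": np.arange(5), "b": np.array([1.0])})

    def test_injected_graded_effect_detected_by_kruskal(self, rng):
        groups = {f"sf_{i}": rng.normal(loc=i * 0.5, size=200)
                  for i in range(5)}
        rep = compare_conditions(groups)
        assert rep.test == "kruskal"
        assert rep.p_value < 0.01
        assert rep.posthoc["p_adjusted"].min() < 0.01
        assert (rep.posthoc["p_adjusted"] >= rep.posthoc["p_raw"] - 1e-12).all()


class TestCharacterizeResponse:
    def test_stronger_pulse_never_delays_detected_onset(self):
        """Average detected onset is non-increasing in injected peak: a
        stronger velocity pulse crosses the confidence bands no later."""
        from dataclasses import replace
        mean_onsets = []
        for peak in (25.0, 45.0, 70.0):
            p = dp.make_preset("monkey_A")
            p = replace(p, pulse=replace(p.pulse, peak=peak))
            onsets = []
            for seed in (1, 2, 3):
                res = dp.drift_response_experiment(p, n_per_condition=150,
                                                   seed=seed)
                assert res.estimate.onset is not None
                onsets.append(res.estimate.onset)
            mean_onsets.append(np.mean(onsets))
        assert mean_onsets[0] >= mean_onsets[1] >= mean_onsets[2] - 1.0

    def test_no_pulse_gives_null_onset(self):
        p = dp.make_preset("monkey_A")
        from dataclasses import replace
        p = replace(p, pulse=replace(p.pulse, peak=0.0, h_tilt=0.0),
                    msac=replace(p.msac, rate=0.0))
        res = dp.drift_response_experiment(p, n_per_condition=40, seed=3)
        assert res.estimate.onset is None
        assert res.estimate.duration is None

    def test_min_trial_rule_enforced(self, small_experiment):
        ens = dp.align_positions(small_experiment)
        few = AlignedEnsemble(t=ens.t, x=ens.x[:5], y=ens.y[:5],
                              vx=ens.vx[:5], vy=ens.vy[:5],
                              valid=ens.valid[:5], conditions=ens.conditions[:5],
                              trial_ids=ens.trial_ids[:5])
        with pytest.raises(ValueError, match=">= 10"):
            dp.characterize_response(few, few)
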