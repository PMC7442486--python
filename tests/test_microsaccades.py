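"""Rate curves, inhibition recovery, time-binned partial averaging and
first-microsaccade direction statistics."""

from dataclasses import replace

import numpy as np
import pytest

import driftpulse as dp
from driftpulse.events import EventInterval, detect_all
from driftpulse.microsaccades import (bin_by_microsaccade_time,
                                      first_microsaccade_directions,
                                      fit_inhibition,
                                      partial_average_velocity, rate_curve)


def _ev(trial_id, onset, kind="microsaccade", amplitude=12.0, direction=0.0):
    return EventInterval(trial_id, kind, onset, onset + 20, amplitude, 15.0,
                         direction)


class TestRateCurve:
    def test_no_events_all_zero(self):
        c = rate_curve({0: []}, n_trials=5)
        assert np.all(c.rate == 0)
        assert c.centers[0] == -300 and c.centers[-1] == 600

    def test_single_event_rectangle(self):
        """One event at 0 ms in one trial -> 12.5/s wherever the 80-ms
        window covers 0, and 0 elsewhere (direct counting)."""
        c = rate_curve({0: [_ev(0, 0.0)]}, n_trials=1)
        inside = np.abs(c.centers) <= 40
        assert np.allclose(c.rate[inside], 1 / 0.080)
        assert np.all(c.rate[~inside] == 0)

    def test_matches_bruteforce_counting_oracle(self, rng):
        events = {i: [_ev(i, float(o))
                      for o in rng.uniform(-350, 650, rng.integers(0, 5))]
                  for i in range(30)}
        c = rate_curve(events, n_trials=30)
        onsets = [e.onset for evs in events.values() for e in evs]
        for j, center in enumerate(c.centers):
            count = sum(center - 40 <= o <= center + 40 for o in onsets)
            assert c.rate[j] == count / (30 * 0.080)

    def test_homogeneous_poisson_recovers_flat_rate(self):
        p = dp.make_preset("monkey_M")
        ts = dp.simulate_experiment(p, 1000, ["none"], seed=17)
        events = {tr.trial_id: [_ev(tr.trial_id, e.onset) for e in tr.events]
                  for tr in ts}
        c = rate_curve(events, n_trials=1000)
        sel = (c.centers > -250) & (c.centers < 550)
        # MC SD of a window count: sqrt(rate*w*n)/(n*w)
        sd = np.sqrt(p.msac.rate * 0.08 * 1000) / (1000 * 0.08)
        assert np.all(np.abs(c.rate[sel] - p.msac.rate) <= 3.5 * sd)
        assert abs(c.rate[sel].mean() - p.msac.rate) <= 3 * sd / np.sqrt(10)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            rate_curve({}, n_trials=0)


class TestInhibitionRecovery:
    def test_depth_and_trough_recovered_from_fit(self):
        """Injected inhibition parameters come back from the fitted
        window-averaged profile within +/-15 ms and +/-0.1 depth."""
        p = dp.make_preset("monkey_M")
        ts = dp.simulate_experiment(p, 1000, ["black_flash"], seed=23)
        events = {tr.trial_id: [_ev(tr.trial_id, e.onset) for e in tr.events]
                  for tr in ts}
        c = rate_curve(events, n_trials=1000)
        base, depth, trough = fit_inhibition(c, p)
        assert abs(trough - p.msac.trough) <= 15
        assert abs(depth - p.msac.depth) <= 0.1
        assert base == pytest.approx(p.msac.rate, rel=0.15)


class TestBinning:
    def test_containment_and_overlap_rules(self, quiet_preset):
        trs = [dp.simulate_trial(quiet_preset, "none", seed=1, trial_index=i)
               for i in range(3)]
        for i, tr in enumerate(trs):
            tr.trial_id = i
        ts = dp.TrialSet(trs)
        events = {0: [_ev(0, -60.0)], 1: [_ev(1, 100.0)], 2: []}
        bins = [(-100.0, -50.0), (50.0, 150.0)]
        out = bin_by_microsaccade_time(ts, events, bins)
        assert [tr.trial_id for tr in out[(-100.0, -50.0)]] == [0]
        assert [tr.trial_id for tr in out[(50.0, 150.0)]] == [1]
        with pytest.raises(ValueError, match="overlap"):
            bin_by_microsaccade_time(ts, events, [(0, 100), (50, 150)])

    def test_zero_rate_all_bins_empty(self, quiet_preset):
        ts = dp.simulate_experiment(quiet_preset, 5, ["none"], 1)
        out = bin_by_microsaccade_time(ts, {tr.trial_id: [] for tr in ts},
                                       [(-100.0, 0.0), (100.0, 200.0)])
        assert all(len(s) == 0 for s in out.values())

    def test_small_bins_dropped_from_averaging(self, small_experiment):
        events = {tr.trial_id: detect_all(tr) for tr in small_experiment}
        bins = [(-100.0, 0.0), (5000.0, 6000.0)]   # second bin out of range
        sets = bin_by_microsaccade_time(small_experiment, events, bins)
        out = partial_average_velocity(sets, events)
        assert (5000.0, 6000.0) not in out         # <10 trials -> dropped

    def test_response_amplitude_independent_of_microsaccade_timing(self):
        """The injected pulse does not depend on microsaccade timing, so
        per-bin peak responses agree across bins."""
        p = dp.make_preset("monkey_A")
        p = replace(p, msac=replace(p.msac, rate=3.0))   # populate the bins
        ts = dp.simulate_experiment(p, 250, ["black_flash"], seed=29)
        events = {tr.trial_id: detect_all(tr) for tr in ts}
        bins = [(-100.0, -25.0), (225.0, 300.0)]
        sets = bin_by_microsaccade_time(ts, events, bins)
        out = partial_average_velocity(sets, events, peak_window=(50, 140))
        assert len(out) == 2
        peaks = [v["peak"] for v in out.values()]
        assert abs(peaks[0] - peaks[1]) < 12     # min arc/s, noise-limited

    def test_mask_before_zero_leaves_poststimulus_band_unchanged(self,
                                                                 quiet_preset):
        ts = dp.simulate_experiment(quiet_preset, 12, ["black_flash"], 1)
        masked_events = {tr.trial_id: [_ev(tr.trial_id, -300.0, "blink")]
                         for tr in ts}
        ens_plain = dp.align_positions(ts)
        ens_mask = dp.align_positions(ts, events=masked_events)
        b0 = dp.average_with_ci(ens_plain, "vy")
        b1 = dp.average_with_ci(ens_mask, "vy")
        sel = ens_plain.t >= 0
        np.testing.assert_allclose(b1.mean[sel], b0.mean[sel], equal_nan=True)


class TestFirstMicrosaccadeDirections:
    def test_rightward_mass_and_exclusions(self, quiet_preset):
        trs = [dp.simulate_trial(quiet_preset, "none", seed=1, trial_index=i)
               for i in range(4)]
        for i, tr in enumerate(trs):
            tr.trial_id = i
        ts = dp.TrialSet(trs)
        events = {0: [_ev(0, 250.0, direction=0.0)],
                  1: [_ev(1, 300.0, direction=0.0)],
                  2: [_ev(2, 100.0, direction=90.0)],   # inside epoch: ignored
                  3: []}
        s = first_microsaccade_directions(ts, events, after=200.0)
        assert s.histogram[0] == 2 and s.histogram[1:].sum() == 0
        assert s.n_excluded == 2
        assert s.circular_mean == pytest.approx(0.0, abs=1e-9)

    def test_circular_mean_matches_direct_computation(self, rng):
        dirs = rng.uniform(0, 360, 40)
        trs = []
        events = {}
        quiet = dp.make_preset("monkey_A", noise_sd=0.0, diffusion=0.0,
                               fixation_sd=0.0)
        quiet = replace(quiet, msac=replace(quiet.msac, rate=0.0))
        for i, d in enumerate(dirs):
            tr = dp.simulate_trial(quiet, "none", seed=1, trial_index=i)
            tr.trial_id = i
            trs.append(tr)
            events[i] = [_ev(i, 250.0, direction=float(d))]
        s = first_microsaccade_directions(dp.TrialSet(trs), events)
        z = np.exp(1j * np.deg2rad(dirs)).mean()
        assert s.circular_mean == pytest.approx(np.degrees(np.angle(z)) % 360,
                                                abs=1e-9)
        assert s.resultant_length == pytest.approx(abs(z), abs=1e-12)

    def test_no_direction_bias_after_simulated_response(self):
        """Simulator injects no post-response direction bias: stimulus and
        control vertical components are statistically indistinguishable."""
        p = dp.make_preset("monkey_M")
        ts = dp.simulate_experiment(p, 250, ["black_flash", "none"], seed=31)
        events = {tr.trial_id: [_ev(tr.trial_id, e.onset,
                                    amplitude=e.amplitude,
                                    direction=e.direction)
                                for e in tr.events if e.kind == "microsaccade"]
                  for tr in ts}
        stim = first_microsaccade_directions(ts.select("black_flash"), events)
        ctrl = first_microsaccade_directions(ts.select("none"), events)
        rep = dp.compare_conditions({"stim": stim.vertical,
                                     "ctrl": ctrl.vertical})
        assert rep.p_value > 0.05
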