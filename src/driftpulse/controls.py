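"""Control analyses: starting-position split, binocularity/vergence, head
movement, electronic calibration drift, and pupil-latency ordering.

These batteries establish that a detected drift response is a genuine
binocular eye rotation rather than a measurement artifact: it must survive
a median split on starting eye position, show no accompanying vergence or
head-channel change, dwarf any slow electronic calibration drift, and
precede the (much slower) stimulus-evoked pupil constriction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import TrialSet
from .kinematics import AlignedEnsemble, FilterParams, estimate_velocity
from .response import piecewise_linear_onset
from .simulate import MIN_ARC_PER_DEG


@dataclass
class PairedIntervalStat:
    """Rank-sum comparison of per-trial mean velocity between a pre-stimulus
    baseline window and a post-stimulus response window."""

    channel: str
    baseline_window: tuple[float, float]
    response_window: tuple[float, float]
    baseline: np.ndarray          # per-trial means
    response: np.ndarray
    statistic: float
    p_value: float
    direction: str                # "increase" | "decrease" | "none"

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def median_split(ts: TrialSet, pre_window: float = 50.0
                 ) -> tuple[TrialSet, TrialSet]:
    """Split trials at the pooled median starting vertical position.

    Starting position is the mean vertical position over the final
    ``pre_window`` ms before stimulus onset; ties go below.
    """
    if len(ts) < 2:
        raise ValueError("median split needs >= 2 trials")
    starts = []
    for tr in ts:
        i1 = tr.index_of(0)
        i0 = tr.index_of(-pre_window)
        starts.append(float(np.nanmean(tr.y[i0:i1])))
    starts_arr = np.array(starts)
    med = float(np.median(starts_arr))
    below = [tr for tr, s in zip(ts, starts_arr) if s <= med]
    above = [tr for tr, s in zip(ts, starts_arr) if s > med]
    prov = dict(ts.provenance)
    return (TrialSet(below, fs=ts.fs, provenance=prov),
            TrialSet(above, fs=ts.fs, provenance=prov))


def paired_interval_stat(trace: np.ndarray, t: np.ndarray, channel: str,
                         baseline_window: tuple[float, float] = (-100.0, 0.0),
                         response_window: tuple[float, float] = (50.0, 150.0)
                         ) -> PairedIntervalStat:
    """Rank-sum on per-trial mean values of ``trace`` (n_trials, n_samples)
    between the two intervals."""
    def win_mean(w):
        sel = (t >= w[0]) & (t <= w[1])
        return np.nanmean(trace[:, sel], axis=1)

    base = win_mean(baseline_window)
    resp = win_mean(response_window)
    res = stats.ranksums(base, resp)
    mb, mr = np.median(base), np.median(resp)
    direction = "increase" if mr > mb else "decrease" if mr < mb else "none"
    return PairedIntervalStat(channel, baseline_window, response_window,
                              base, resp, float(res.statistic),
                              float(res.pvalue), direction)


def _stack_velocity(ts: TrialSet, attr: str,
                    params: FilterParams = FilterParams()) -> np.ndarray:
    rows = [getattr(tr, attr) for tr in ts]
    if any(r is None for r in rows):
        raise ValueError(f"channel {attr!r} missing from some trials")
    return estimate_velocity(np.vstack(rows), fs=ts.fs, params=params)


@dataclass
class VergenceReport:
    vergence: PairedIntervalStat       # on vergence velocity
    eye1_vertical: PairedIntervalStat
    eye2_vertical: PairedIntervalStat


def vergence_check(ts: TrialSet) -> VergenceReport:
    """Paired-interval rank-sum on vergence velocity plus both eyes' vertical
    responses.  Vergence = left_x - right_x (second channel minus first);
    positive change = convergence.  Requires binocular trials.
    """
    if not len(ts) or ts[0].x2 is None:
        raise ValueError("vergence check requires binocular (two-eye) trials")
    t = ts[0].t
    verg = np.vstack([tr.x2 - tr.x for tr in ts])
    v_verg = estimate_velocity(verg, fs=ts.fs)
    return VergenceReport(
        vergence=paired_interval_stat(v_verg, t, "vergence_velocity"),
        eye1_vertical=paired_interval_stat(_stack_velocity(ts, "y"), t,
                                           "eye1_vertical_velocity"),
        eye2_vertical=paired_interval_stat(_stack_velocity(ts, "y2"), t,
                                           "eye2_vertical_velocity"))


def head_movement_check(ts: TrialSet) -> dict[str, PairedIntervalStat]:
    """Paired-interval rank-sums for both differentiated head channels and
    the vertical eye channel (same smoothing differentiator for all).

    On a genuine drift response the eye channel is significant and the head
    channels are not.
    """
    if not len(ts) or ts[0].head_a is None:
        raise ValueError("head check requires head channels")
    t = ts[0].t
    return {
        "eye_vertical": paired_interval_stat(_stack_velocity(ts, "y"), t,
                                             "eye_vertical_velocity"),
        "head_a": paired_interval_stat(_stack_velocity(ts, "head_a"), t,
                                       "head_a_velocity"),
        "head_b": paired_interval_stat(_stack_velocity(ts, "head_b"), t,
                                       "head_b_velocity"),
    }


@dataclass
class ElectronicDriftReport:
    slope_minarc_per_trial: float
    speed_minarc_per_s: float          # slope over the session time base
    physiological_speed: float         # baseline drift speed, min arc/s
    ratio: float                       # physiological / electronic
    flagged: bool                      # True unless ratio >= 10


def electronic_drift_speed(ts: TrialSet, pre_window: float = 30.0,
                           trial_spacing_s: float = 5.0,
                           min_trials: int = 20) -> ElectronicDriftReport:
    """Slow calibration drift of the coil system across a session.

    Fits the mean vertical position in the final ``pre_window`` ms before
    (sham) stimulus onset against cumulative session time.  The slope is an
    'electronic drift speed'; it is compared with the physiological baseline
    drift speed (median per-trial pre-stimulus velocity magnitude) and
    flagged unless at least an order of magnitude slower.
    """
    if len(ts) < min_trials:
        raise ValueError(f"need >= {min_trials} trials")
    if trial_spacing_s <= 0:
        raise ValueError("unknown or invalid trial spacing")
    pre = []
    vmag = []
    for tr in ts:
        i1 = tr.index_of(0)
        i0 = tr.index_of(-pre_window)
        pre.append(float(np.nanmean(tr.y[i0:i1])) * MIN_ARC_PER_DEG)
        vx = estimate_velocity(tr.x, fs=tr.fs)
        vy = estimate_velocity(tr.y, fs=tr.fs)
        b0 = tr.index_of(-100)
        vmag.append(np.hypot(np.nanmean(vx[b0:i1]), np.nanmean(vy[b0:i1]))
                    * MIN_ARC_PER_DEG)
    idx = np.arange(len(ts), dtype=float)
    slope = float(np.polyfit(idx, np.array(pre), 1)[0])      # min arc / trial
    speed = slope / trial_spacing_s
    phys = float(np.median(vmag))
    ratio = phys / abs(speed) if speed != 0 else np.inf
    return ElectronicDriftReport(slope_minarc_per_trial=slope,
                                 speed_minarc_per_s=speed,
                                 physiological_speed=phys, ratio=float(ratio),
                                 flagged=bool(ratio < 10.0))


@dataclass
class PupilReport:
    t: np.ndarray
    mean_trace: np.ndarray             # baseline-subtracted average, a.u.
    onset: float | None                # piecewise-linear constriction onset, ms
    drift_onset: float | None
    pupil_later: bool | None           # True iff pupil onset > drift onset


def pupil_response(ts: TrialSet, drift_onset: float | None = None,
                   baseline_window: float = 100.0,
                   search: tuple[float, float] = (0.0, 400.0)) -> PupilReport:
    """Baseline-subtracted mean pupil trace and its constriction onset.

    Each trial's mean pupil diameter over the final ``baseline_window`` ms
    before stimulus onset is subtracted before averaging (units are
    arbitrary, so only onsets and signs are interpreted).  The onset is the
    hinge-fit breakpoint of the average trace; when ``drift_onset`` is given
    the report states whether the constriction came later.
    """
    if not len(ts) or ts[0].pupil is None:
        raise ValueError("pupil channel missing")
    t = ts[0].t
    rows = []
    for tr in ts:
        i1 = tr.index_of(0)
        i0 = tr.index_of(-baseline_window)
        rows.append(tr.pupil - np.nanmean(tr.pupil[i0:i1]))
    mean_trace = np.nanmean(np.vstack(rows), axis=0)
    onset = piecewise_linear_onset(t, mean_trace, search=search)
    later = None
    if onset is not None and drift_onset is not None:
        later = bool(onset > drift_onset)
    return PupilReport(t=t.copy(), mean_trace=mean_trace, onset=onset,
                       drift_onset=drift_onset, pupil_later=later)
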