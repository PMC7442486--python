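"""Saccade/microsaccade and blink detection, saccade-free epoch filtering.

Saccades are detected with the Engbert-Kliegl median-estimator velocity
threshold: per-component noise scale ``sigma = sqrt(median(v^2) -
median(v)^2)``, elliptic criterion ``(vx/(lambda*sx))^2 +
(vy/(lambda*sy))^2 > 1`` with ``lambda = 6``, minimum duration 6 ms, events
closer than 20 ms merged.  Events with amplitude below 1 deg are classified
as microsaccades.  Blinks are signal dropouts or >20 deg excursions, padded
by a +/-50 ms guard margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrialSet
from .kinematics import FilterParams, estimate_velocity
from .simulate import MIN_ARC_PER_DEG, Trial


@dataclass(frozen=True)
class DetectionParams:
    lam: float = 6.0               # threshold multiplier on the median scale
    min_duration_ms: float = 6.0
    merge_gap_ms: float = 20.0
    microsaccade_ceiling: float = 60.0   # min arc; below -> microsaccade
    min_peak_velocity: float = 3.0       # deg/s; rejects sub-saccadic crossings
    refine_frac: float = 0.25      # onset/offset at this fraction of event peak
    min_sigma: float = 0.02        # deg/s floor for the noise scale
    filter: FilterParams = FilterParams()


@dataclass(frozen=True)
class BlinkParams:
    excursion_deg: float = 20.0
    pad_ms: float = 50.0


@dataclass(frozen=True)
class EventInterval:
    """A detected saccade, microsaccade or blink with kinematic summary."""

    trial_id: int
    kind: str                  # "saccade" | "microsaccade" | "blink"
    onset: float               # ms
    offset: float              # ms
    amplitude: float           # min arc
    peak_velocity: float       # deg/s
    direction: float           # deg, 0 = rightward, CCW positive

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("event offset must exceed onset")
        if self.amplitude < 0:
            raise ValueError("event amplitude must be non-negative")

    def overlaps(self, window: tuple[float, float]) -> bool:
        return self.onset <= window[1] and self.offset >= window[0]


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def detect_saccades(trial: Trial, params: DetectionParams = DetectionParams()
                    ) -> list[EventInterval]:
    """Engbert-Kliegl velocity-threshold detection on one trial."""
    vx = estimate_velocity(trial.x, fs=trial.fs, params=params.filter)
    vy = estimate_velocity(trial.y, fs=trial.fs, params=params.filter)
    finite = np.isfinite(vx) & np.isfinite(vy)
    if finite.sum() < 10:
        raise ValueError("trial too short for velocity-based detection")

    def med_scale(v: np.ndarray) -> float:
        vv = v[finite]
        s2 = np.median(vv ** 2) - np.median(vv) ** 2
        return max(np.sqrt(max(s2, 0.0)), params.min_sigma)

    ex = params.lam * med_scale(vx)
    ey = params.lam * med_scale(vy)
    above = np.zeros(trial.t.size, dtype=bool)
    above[finite] = (vx[finite] / ex) ** 2 + (vy[finite] / ey) ** 2 > 1.0

    runs = _bool_runs(above)
    dt_ms = 1000.0 / trial.fs
    # merge runs separated by less than the merge gap
    merged: list[list[int]] = []
    for lo, hi in runs:
        if merged and (lo - merged[-1][1]) * dt_ms < params.merge_gap_ms:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])

    events: list[EventInterval] = []
    speed = np.hypot(vx, vy)
    for lo, hi in merged:
        if (hi - lo) * dt_ms < params.min_duration_ms:
            continue
        # saccades are fast: a peak-velocity floor keeps the detector blind
        # to slow drift modulations (<~1 deg/s) that can graze the
        # median-based threshold during the response itself
        if np.nanmax(speed[lo:hi]) < params.min_peak_velocity:
            continue
        # the symmetric smoothing differentiator spreads saccadic velocity
        # backwards/forwards in time, so threshold crossings overshoot the
        # movement bounds; refine them to where speed reaches a fraction of
        # this event's own peak (never below the detection threshold)
        peak = float(np.nanmax(speed[lo:hi]))
        cut = max(params.refine_frac * peak, min(ex, ey))
        inside = np.flatnonzero(speed[lo:hi] >= cut)
        if inside.size:
            lo, hi = lo + inside[0], lo + inside[-1] + 1
        dx = trial.x[hi - 1] - trial.x[lo]
        dy = trial.y[hi - 1] - trial.y[lo]
        amp = float(np.hypot(dx, dy) * MIN_ARC_PER_DEG)
        kind = "microsaccade" if amp < params.microsaccade_ceiling else "saccade"
        events.append(EventInterval(
            trial_id=trial.trial_id, kind=kind,
            onset=float(trial.t[lo]), offset=float(trial.t[hi - 1]),
            amplitude=amp,
            peak_velocity=float(np.nanmax(speed[lo:hi])),
            direction=float(np.degrees(np.arctan2(dy, dx)))))
    return events


def detect_blinks(trial: Trial, params: BlinkParams = BlinkParams()
                  ) -> list[EventInterval]:
    """Signal-loss / excursion intervals, padded and clipped to the trace."""
    bad = (np.isnan(trial.x) | np.isnan(trial.y)
           | (np.abs(np.nan_to_num(trial.x)) > params.excursion_deg)
           | (np.abs(np.nan_to_num(trial.y)) > params.excursion_deg))
    dt_ms = 1000.0 / trial.fs
    pad = int(round(params.pad_ms / dt_ms))
    events = []
    last_hi = None
    for lo, hi in _bool_runs(bad):
        lo = max(0, lo - pad)
        hi = min(trial.t.size, hi + pad)
        if last_hi is not None and lo <= last_hi:
            prev = events.pop()
            lo = int(round(prev.onset - trial.t[0]))
        events.append(EventInterval(
            trial_id=trial.trial_id, kind="blink",
            onset=float(trial.t[lo]), offset=float(trial.t[hi - 1]),
            amplitude=0.0, peak_velocity=0.0, direction=0.0))
        last_hi = hi
    return events


def detect_all(trial: Trial, params: DetectionParams = DetectionParams(),
               blink_params: BlinkParams = BlinkParams()) -> list[EventInterval]:
    ev = detect_blinks(trial, blink_params) + detect_saccades(trial, params)
    return sorted(ev, key=lambda e: e.onset)


def is_saccade_free(trial: Trial, events: list[EventInterval],
                    window: tuple[float, float]) -> bool:
    """True iff no saccade/microsaccade/blink overlaps ``window`` (ms)."""
    if window[0] < trial.t[0] or window[1] > trial.t[-1]:
        raise ValueError(f"window {window} outside trial span "
                         f"[{trial.t[0]}, {trial.t[-1]}]")
    return not any(e.overlaps(window) for e in events)


def filter_saccade_free(ts: TrialSet, window: tuple[float, float] = (-100, 200),
                        events: dict[int, list[EventInterval]] | None = None,
                        params: DetectionParams = DetectionParams()
                        ) -> tuple[TrialSet, pd.DataFrame]:
    """Keep trials with no saccadic or blink event inside ``window``.

    ``events`` may carry pre-detected events per trial_id; otherwise
    detection runs here.  Returns the retained subset (original order) and a
    per-condition report of retained/excluded counts.
    """
    if events is None:
        events = {tr.trial_id: detect_all(tr, params) for tr in ts}
    kept = []
    counts: dict[str, dict[str, int]] = {}
    for tr in ts:
        ok = is_saccade_free(tr, events.get(tr.trial_id, []), window)
        c = counts.setdefault(tr.condition, {"retained": 0, "excluded": 0})
        c["retained" if ok else "excluded"] += 1
        if ok:
            kept.append(tr)
    report = pd.DataFrame(
        [{"condition": k, **v} for k, v in counts.items()],
        columns=["condition", "retained", "excluded"])
    return TrialSet(kept, fs=ts.fs, provenance=dict(ts.provenance)), report


def velocity_outlier_check(trial: Trial, ceiling: float = 3.0,
                           events: list[EventInterval] = (),
                           params: DetectionParams = DetectionParams()) -> bool:
    """Sanity check against 1-ms electronic artifacts.

    Returns False (reject) iff any smoothed-velocity sample outside detected
    events exceeds ``ceiling`` (deg/s).  Event masks are padded by the
    filter half-window, where saccadic velocity still bleeds into the
    smoothed trace.
    """
    if not np.isfinite(ceiling):
        return True
    vx = estimate_velocity(trial.x, fs=trial.fs, params=params.filter)
    vy = estimate_velocity(trial.y, fs=trial.fs, params=params.filter)
    speed = np.hypot(vx, vy)
    free = np.isfinite(speed)
    dt_ms = 1000.0 / trial.fs
    pad = params.filter.window_ms // 2 + 1
    for e in events:
        lo = max(0, int(round((e.onset - trial.t[0]) / dt_ms)) - pad)
        hi = min(trial.t.size,
                 int(round((e.offset - trial.t[0]) / dt_ms)) + 1 + pad)
        free[lo:hi] = False
    return not np.any(speed[free] > ceiling)


def events_to_frame(events: dict[int, list[EventInterval]]) -> pd.DataFrame:
    rows = [{"trial_id": e.trial_id, "kind": e.kind, "onset_ms": e.onset,
             "offset_ms": e.offset, "amplitude_minarc": e.amplitude,
             "peak_velocity_degs": e.peak_velocity, "direction_deg": e.direction}
            for evs in events.values() for e in evs]
    return pd.DataFrame(rows, columns=["trial_id", "kind", "onset_ms",
                                       "offset_ms", "amplitude_minarc",
                                       "peak_velocity_degs", "direction_deg"])
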