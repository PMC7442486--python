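"""Saccadic-inhibition rate curves and microsaccade-conditioned averaging.

Microsaccade rate is estimated with a running 80-ms window stepped in 5-ms
increments from -300 to +600 ms around stimulus onset, normalized to
movements per second.  Windows are centered on their timestamp (a trailing
variant is available; the choice shifts curves by at most half a window and
all trough-relative statements are robust to it).  Trials can further be
binned by the timing of their microsaccades so that the non-saccadic
portion of eye velocity is averaged per bin, and the direction of the first
microsaccade after the saccade-free epoch can be compared between stimulus
and control trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .events import EventInterval
from .io import TrialSet
from .kinematics import AlignedEnsemble, align_positions
from .response import CIBand, average_with_ci, peak_in_window
from .simulate import MIN_ARC_PER_DEG, SimPreset, microsaccade_rate_profile


@dataclass
class RateCurve:
    """Running-window microsaccade rate (/s) around stimulus onset."""

    centers: np.ndarray       # ms
    rate: np.ndarray          # /s
    width: float              # ms
    step: float               # ms
    n_trials: int


def _event_onsets(events: dict[int, list[EventInterval]],
                  kinds: tuple[str, ...] = ("microsaccade", "saccade")
                  ) -> np.ndarray:
    return np.array([e.onset for evs in events.values() for e in evs
                     if e.kind in kinds], dtype=float)


def rate_curve(events: dict[int, list[EventInterval]], n_trials: int,
               width: float = 80.0, step: float = 5.0,
               trange: tuple[float, float] = (-300.0, 600.0),
               centered: bool = True) -> RateCurve:
    """rate(t) = count of event onsets in [t-w/2, t+w/2] / (n_trials * w).

    With ``centered=False`` the window trails its timestamp ([t-w, t]).
    Events are counted by onset time only; window bounds are inclusive.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    onsets = _event_onsets(events)
    centers = np.arange(trange[0], trange[1] + step / 2, step)
    if centered:
        lo, hi = centers - width / 2, centers + width / 2
    else:
        lo, hi = centers - width, centers
    counts = np.array([(np.sum((onsets >= a) & (onsets <= b)) if onsets.size
                        else 0) for a, b in zip(lo, hi)], dtype=float)
    return RateCurve(centers=centers, rate=counts / (n_trials * width / 1000.0),
                     width=width, step=step, n_trials=n_trials)


def fit_inhibition(curve: RateCurve, preset: SimPreset
                   ) -> tuple[float, float, float]:
    """Recover (baseline rate, inhibition depth, trough time) from a curve.

    Least-squares fit of the window-averaged parametric inhibition profile,
    which removes the late-argmin bias that the 80-ms running window and the
    slow recovery limb would otherwise impose on a raw minimum search.
    """
    fine = np.arange(curve.centers[0] - curve.width, curve.centers[-1]
                     + curve.width + 1.0)
    half = curve.width / 2

    def model(params: np.ndarray) -> np.ndarray:
        base, depth, trough = params
        from dataclasses import replace
        p = replace(preset, msac=replace(preset.msac, rate=base,
                                         depth=depth, trough=trough))
        prof = microsaccade_rate_profile(fine, p, stimulus=True)
        out = np.empty(curve.centers.size)
        for i, c in enumerate(curve.centers):
            sel = (fine >= c - half) & (fine <= c + half)
            out[i] = prof[sel].mean()
        return out

    def resid(params: np.ndarray) -> np.ndarray:
        return model(params) - curve.rate

    base0 = max(float(np.mean(curve.rate[curve.centers < -100])), 0.1)
    res = least_squares(resid, x0=[base0, 0.8, 120.0],
                        bounds=([0.01, 0.0, 20.0], [20.0, 1.0, 400.0]))
    base, depth, trough = res.x
    return float(base), float(depth), float(trough)


def bin_by_microsaccade_time(ts: TrialSet,
                             events: dict[int, list[EventInterval]],
                             bins: list[tuple[float, float]]
                             ) -> dict[tuple[float, float], TrialSet]:
    """Assign each trial to every bin containing >= 1 microsaccade onset.

    Bins must be disjoint time ranges (ms relative to stimulus onset).
    """
    for i, a in enumerate(bins):
        for b in bins[i + 1:]:
            if a[0] <= b[1] and b[0] <= a[1]:
                raise ValueError(f"overlapping bins {a} and {b}")
    out: dict[tuple[float, float], TrialSet] = {}
    for bin_ in bins:
        members = []
        for tr in ts:
            onsets = [e.onset for e in events.get(tr.trial_id, [])
                      if e.kind in ("microsaccade", "saccade")]
            if any(bin_[0] <= o <= bin_[1] for o in onsets):
                members.append(tr)
        out[tuple(bin_)] = TrialSet(members, fs=ts.fs,
                                    provenance=dict(ts.provenance))
    return out


def partial_average_velocity(bin_sets: dict[tuple[float, float], TrialSet],
                             events: dict[int, list[EventInterval]],
                             peak_window: tuple[float, float] = (50.0, 140.0),
                             min_n: int = 10
                             ) -> dict[tuple[float, float], dict]:
    """Masked per-bin velocity bands and peak response amplitudes.

    Saccadic samples are invalidated so only non-saccadic velocity is
    averaged; bins with fewer than ``min_n`` qualifying trials are dropped
    (too few repetitions to show).
    """
    out = {}
    for bin_, subset in bin_sets.items():
        if len(subset) < min_n:
            continue
        ens = align_positions(subset, events=events)
        band = average_with_ci(ens, "vy", min_n=min_n)
        try:
            peak, lat = peak_in_window(band.t, band.mean * MIN_ARC_PER_DEG,
                                       peak_window)
        except ValueError:
            peak = lat = None
        out[bin_] = {"band": band, "peak": peak, "peak_latency": lat,
                     "n": len(subset)}
    return out


@dataclass
class DirectionSummary:
    """Angular distribution of the first microsaccade after the epoch."""

    directions: np.ndarray         # deg, one per qualifying trial
    vertical: np.ndarray           # vertical displacement components, min arc
    histogram: np.ndarray          # counts in 30-deg bins
    bin_edges: np.ndarray
    circular_mean: float           # deg
    resultant_length: float        # mean resultant vector length in [0, 1]
    n_excluded: int                # trials with no subsequent microsaccade


def first_microsaccade_directions(ts: TrialSet,
                                  events: dict[int, list[EventInterval]],
                                  after: float = 200.0,
                                  bin_width: float = 30.0) -> DirectionSummary:
    """Direction of the first microsaccade following ``after`` ms, per trial.

    Trials without a subsequent microsaccade are excluded and counted.
    Up = 90 deg (mathematical convention).
    """
    dirs, vert = [], []
    excluded = 0
    for tr in ts:
        cands = sorted((e for e in events.get(tr.trial_id, [])
                        if e.kind == "microsaccade" and e.onset > after),
                       key=lambda e: e.onset)
        if not cands:
            excluded += 1
            continue
        e = cands[0]
        dirs.append(e.direction % 360.0)
        vert.append(e.amplitude * np.sin(np.deg2rad(e.direction)))
    dirs_arr = np.array(dirs)
    edges = np.arange(0.0, 360.0 + bin_width / 2, bin_width)
    hist, _ = np.histogram(dirs_arr, bins=edges)
    if dirs_arr.size:
        z = np.exp(1j * np.deg2rad(dirs_arr)).mean()
        cmean = float(np.degrees(np.angle(z)) % 360.0)
        r = float(np.abs(z))
    else:
        cmean, r = float("nan"), 0.0
    return DirectionSummary(directions=dirs_arr, vertical=np.array(vert),
                            histogram=hist, bin_edges=edges,
                            circular_mean=cmean, resultant_length=r,
                            n_excluded=excluded)
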