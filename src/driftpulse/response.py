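"""Confidence-band averaging, CI-divergence onset detection and condition
comparisons — the statistical core of the drift-response analysis.

The response is declared significant where the 95% confidence bands of the
stimulus and control ensembles fail to overlap for at least 20 consecutive
milliseconds; the first such run after t = 0 defines the onset, and the
response ends at the first subsequent >= 20 ms run of band re-overlap.
Velocity bands give the liberal onset estimate; the equivalent computation
on position traces is reported as the conservative one.  Average curves
built from fewer than 10 repetitions are flagged undefined rather than
shown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import AlignedEnsemble, measure_displacement
from .simulate import MIN_ARC_PER_DEG


@dataclass
class CIBand:
    """Per-millisecond mean and 95% confidence band of an ensemble."""

    t: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n: np.ndarray                 # trials contributing per ms
    defined: np.ndarray           # False where n < min_n

    def window_slice(self, window: tuple[float, float]) -> slice:
        i0 = int(round(window[0] - self.t[0]))
        i1 = int(round(window[1] - self.t[0]))
        if i0 < 0 or i1 >= self.t.size:
            raise ValueError(f"window {window} outside band axis")
        return slice(i0, i1 + 1)


def average_with_ci(ens: AlignedEnsemble, channel: str = "vy",
                    level: float = 0.95, min_n: int = 10,
                    method: str = "t", n_boot: int = 1000,
                    rng: np.random.Generator | None = None) -> CIBand:
    """Masked per-ms mean with a 95% confidence band.

    ``method='t'`` uses mean +/- t(0.975, n-1)*SEM; ``method='bootstrap'``
    uses the percentile band of ``n_boot`` trial resamples.  Times with
    fewer than ``min_n`` valid trials are flagged undefined (never an
    error).
    """
    if ens.n_trials == 0:
        raise ValueError("empty ensemble")
    data = getattr(ens, channel)
    ok = ens.valid & np.isfinite(data)
    vals = np.where(ok, data, 0.0)
    n = ok.sum(axis=0)
    nn = np.maximum(n, 1)
    mean = np.where(n > 0, vals.sum(axis=0) / nn, np.nan)
    defined = n >= min_n

    if method == "t":
        ss = (np.where(ok, (data - mean) ** 2, 0.0)).sum(axis=0)
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
        sem = np.where(n > 1, sd / np.sqrt(nn), np.nan)
        crit = stats.t.ppf(0.5 + level / 2, np.maximum(n - 1, 1))
        lo = mean - crit * sem
        hi = mean + crit * sem
    elif method == "bootstrap":
        rng = rng or np.random.default_rng(0)
        boots = np.empty((n_boot, vals.shape[1]))
        for b in range(n_boot):
            idx = rng.integers(0, vals.shape[0], size=vals.shape[0])
            nb = ok[idx].sum(axis=0)
            boots[b] = np.where(nb > 0,
                                vals[idx].sum(axis=0) / np.maximum(nb, 1),
                                np.nan)
        q = (1 - level) / 2
        lo = np.nanquantile(boots, q, axis=0)
        hi = np.nanquantile(boots, 1 - q, axis=0)
    else:
        raise ValueError("method must be 't' or 'bootstrap'")
    lo = np.where(defined, lo, np.nan)
    hi = np.where(defined, hi, np.nan)
    return CIBand(t=ens.t.copy(), mean=np.where(n > 0, mean, np.nan),
                  lo=lo, hi=hi, n=n, defined=defined)


@dataclass(frozen=True)
class Run:
    start: float      # ms
    length: float     # ms

    @property
    def stop(self) -> float:
        return self.start + self.length


@dataclass
class DivergenceRuns:
    """All maximal non-overlap runs between two bands.

    ``significant`` keeps only runs of at least the minimum length; shorter
    flickers are retained in ``runs`` for display but carry no weight.
    """

    runs: list[Run]
    significant: list[Run]
    min_run: float


def _runs_from_mask(t: np.ndarray, mask: np.ndarray, dt: float) -> list[Run]:
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return [Run(start=float(t[lo]), length=float((hi - lo) * dt))
            for lo, hi in zip(idx[::2], idx[1::2])]


def band_nonoverlap(a: CIBand, b: CIBand) -> np.ndarray:
    """Boolean per-ms mask where the two 95% bands are disjoint."""
    if a.t.size != b.t.size or a.t[0] != b.t[0]:
        raise ValueError("bands must share one time axis")
    both = a.defined & b.defined
    with np.errstate(invalid="ignore"):
        apart = (a.lo > b.hi) | (b.lo > a.hi)
    return both & np.nan_to_num(apart, nan=False).astype(bool)


def detect_divergence(a: CIBand, b: CIBand, min_run: float = 20.0,
                      t_min: float | None = None) -> DivergenceRuns:
    """Maximal runs where the bands fail to overlap.

    Runs shorter than ``min_run`` ms are reported but not significant.
    ``t_min`` restricts run starts (onset search is limited to t >= 0 in the
    response pipeline; earlier divergences are anomalies, not onsets).
    """
    mask = band_nonoverlap(a, b)
    dt = float(a.t[1] - a.t[0])
    runs = _runs_from_mask(a.t, mask, dt)
    if t_min is not None:
        runs = [r for r in runs if r.start >= t_min]
    return DivergenceRuns(runs=runs,
                          significant=[r for r in runs if r.length >= min_run],
                          min_run=min_run)


def peak_in_window(t: np.ndarray, trace: np.ndarray,
                   window: tuple[float, float]) -> tuple[float, float]:
    """Maximum of ``trace`` and its time within ``window`` (earliest tie wins).

    Raises if the window contains no defined samples.
    """
    i0 = int(round(window[0] - t[0]))
    i1 = int(round(window[1] - t[0]))
    if i0 < 0 or i1 >= t.size:
        raise ValueError(f"window {window} outside time axis")
    seg = np.asarray(trace, dtype=float)[i0:i1 + 1]
    if np.all(np.isnan(seg)):
        raise ValueError("window is undefined throughout")
    k = int(np.nanargmax(seg))          # first maximum under ties
    return float(seg[k]), float(t[i0 + k])


def per_trial_peaks(ens: AlignedEnsemble, window: tuple[float, float],
                    channel: str = "vy") -> tuple[np.ndarray, np.ndarray]:
    """Per-trial peak value (min arc/s for velocity channels) and latency."""
    data = getattr(ens, channel)
    sl = ens.window_slice(window)
    seg = np.where(ens.valid[:, sl], data[:, sl], np.nan)
    peaks = np.full(ens.n_trials, np.nan)
    lats = np.full(ens.n_trials, np.nan)
    has = ~np.all(np.isnan(seg), axis=1)
    idx = np.zeros(ens.n_trials, dtype=int)
    idx[has] = np.nanargmax(seg[has], axis=1)
    peaks[has] = seg[has, idx[has]]
    lats[has] = ens.t[sl][idx[has]]
    if channel in ("vx", "vy"):
        peaks *= MIN_ARC_PER_DEG
    return peaks, lats


@dataclass
class DriftResponseEstimate:
    """Onset/duration/peak/displacement summary of one stimulus condition.

    ``onset`` is the start of the first >= ``min_run`` ms velocity-band
    divergence at t >= 0; ``offset`` the first post-onset time at which the
    bands re-overlap for >= ``min_run`` consecutive ms; peak velocity is the
    maximum of the control-subtracted mean vertical velocity in the search
    window (min arc/s); ``position_onset`` is the conservative estimate from
    the position-trace bands.  A null onset flags the absence of any
    significant divergence.
    """

    onset: float | None
    duration: float | None
    offset: float | None
    peak_velocity: float | None
    peak_latency: float | None
    displacement: float | None
    position_onset: float | None
    velocity_runs: DivergenceRuns | None = None
    position_runs: DivergenceRuns | None = None
    condition: str = ""

    def as_row(self) -> dict:
        return {"condition": self.condition, "onset_ms": self.onset,
                "duration_ms": self.duration, "offset_ms": self.offset,
                "peak_velocity_minarc_s": self.peak_velocity,
                "peak_latency_ms": self.peak_latency,
                "displacement_minarc": self.displacement,
                "position_onset_ms": self.position_onset}


def characterize_response(stim: AlignedEnsemble, ctrl: AlignedEnsemble,
                          peak_window: tuple[float, float] = (50.0, 140.0),
                          disp_window: tuple[float, float] = (150.0, 200.0),
                          min_run: float = 20.0, min_n: int = 10,
                          ci_method: str = "t",
                          condition: str = "") -> DriftResponseEstimate:
    """Full drift-response characterization of stimulus vs control ensembles.

    Both ensembles must already be saccade-free-filtered and aligned and
    hold at least ``min_n`` trials each.
    """
    if stim.n_trials < min_n or ctrl.n_trials < min_n:
        raise ValueError(f"need >= {min_n} trials per ensemble")

    vband_s = average_with_ci(stim, "vy", min_n=min_n, method=ci_method)
    vband_c = average_with_ci(ctrl, "vy", min_n=min_n, method=ci_method)
    vruns = detect_divergence(vband_s, vband_c, min_run=min_run, t_min=0.0)

    pband_s = average_with_ci(stim, "y", min_n=min_n, method=ci_method)
    pband_c = average_with_ci(ctrl, "y", min_n=min_n, method=ci_method)
    pruns = detect_divergence(pband_s, pband_c, min_run=min_run, t_min=0.0)
    position_onset = pruns.significant[0].start if pruns.significant else None

    onset = duration = offset = None
    if vruns.significant:
        onset = vruns.significant[0].start
        # offset: first post-onset re-overlap persisting >= min_run ms
        overlap = ~band_nonoverlap(vband_s, vband_c)
        dt = float(vband_s.t[1] - vband_s.t[0])
        for r in _runs_from_mask(vband_s.t, overlap, dt):
            if r.start > onset and r.length >= min_run:
                offset = r.start
                break
        if offset is not None:
            duration = offset - onset

    diff = (vband_s.mean - vband_c.mean) * MIN_ARC_PER_DEG
    try:
        peak, peak_lat = peak_in_window(vband_s.t, diff, peak_window)
    except ValueError:
        peak = peak_lat = None
    try:
        disp = measure_displacement(stim, ctrl, disp_window, min_trials=min_n)
    except ValueError:
        disp = None

    return DriftResponseEstimate(
        onset=onset, duration=duration, offset=offset,
        peak_velocity=peak, peak_latency=peak_lat, displacement=disp,
        position_onset=position_onset, velocity_runs=vruns,
        position_runs=pruns, condition=condition)


def piecewise_linear_onset(t: np.ndarray, trace: np.ndarray,
                           search: tuple[float, float] = (0.0, 400.0),
                           fit_span: tuple[float, float] | None = None
                           ) -> float | None:
    """Breakpoint of a continuous two-segment (hinge) least-squares fit.

    The model ``y = a + b*t + c*max(0, t - tau)`` is fit for every candidate
    ``tau`` on a 1-ms grid over ``search``; the breakpoint minimizing the
    residual sum of squares is returned.  Only samples inside ``fit_span``
    (default: from 100 ms before the search window to its end) enter the
    fit — a hinge is a local model of the onset region, and fitting far
    beyond it lets any late curvature of the trace drag the breakpoint
    away.  Degenerate (flat) traces return None.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(trace, dtype=float)
    if fit_span is None:
        fit_span = (search[0] - 100.0, search[1])
    ok = np.isfinite(y) & (t >= fit_span[0]) & (t <= fit_span[1])
    t, y = t[ok], y[ok]
    if t.size < 10 or np.ptp(y) == 0:
        return None
    taus = np.arange(max(search[0], t[2]), min(search[1], t[-3]) + 1.0)
    if taus.size == 0:
        return None
    best_tau, best_sse = None, np.inf
    ones = np.ones_like(t)
    for tau in taus:
        X = np.column_stack([ones, t, np.maximum(0.0, t - tau)])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(res[0]) if res.size else float(np.sum((y - X @ beta) ** 2))
        if sse < best_sse:
            best_sse, best_tau = sse, float(tau)
    return best_tau


@dataclass
class ComparisonReport:
    """Rank-based comparison of per-trial measurements across conditions."""

    test: str                      # "ranksum" | "kruskal"
    statistic: float
    p_value: float
    direction: str                 # for two groups: which median is larger
    groups: list[str]
    posthoc: pd.DataFrame | None = None


def compare_conditions(groups: dict[str, np.ndarray],
                       alpha: float = 0.05) -> ComparisonReport:
    """Wilcoxon rank-sum for two groups; Kruskal-Wallis plus
    Bonferroni-corrected pairwise rank-sums for more."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 conditions")
    arrays = []
    for name in names:
        a = np.asarray(groups[name], dtype=float)
        a = a[np.isfinite(a)]
        if a.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        arrays.append(a)

    if len(names) == 2:
        res = stats.ranksums(arrays[0], arrays[1])
        med = [np.median(a) for a in arrays]
        direction = (f"{names[0]} > {names[1]}" if med[0] > med[1]
                     else f"{names[1]} > {names[0]}" if med[1] > med[0]
                     else "equal")
        return ComparisonReport("ranksum", float(res.statistic),
                                float(res.pvalue), direction, names)

    res = stats.kruskal(*arrays)
    k = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rr = stats.ranksums(arrays[i], arrays[j])
            rows.append({"a": names[i], "b": names[j],
                         "statistic": float(rr.statistic),
                         "p_raw": float(rr.pvalue),
                         "p_adjusted": min(1.0, float(rr.pvalue) * k),
                         "significant": float(rr.pvalue) * k < alpha})
    return ComparisonReport("kruskal", float(res.statistic), float(res.pvalue),
                            "", names, posthoc=pd.DataFrame(rows))
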