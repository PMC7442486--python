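"""Synthetic fixational eye-movement generator with known ground truth.

Emulates 1 kHz scleral-search-coil recordings of a fixating macaque around
the onset of a brief full-field (or split-field / grating) visual transient:

* a stereotyped slow baseline drift plus a positional random walk,
* a stimulus-locked transient velocity pulse in the vertical channel
  (the "drift response": cosine-ramped trapezoid, onset ~60-80 ms,
  plateau ~33-45 min arc/s, net displacement ~2-3 min arc), with a signed
  horizontal tilt for lateralized stimuli and an optional brief initial
  downward dip,
* microsaccades drawn from an inhomogeneous point process whose rate dips
  after stimulus onset (saccadic inhibition), with lognormal amplitudes and
  minimum-jerk waveforms,
* white measurement noise, optional blinks (signal dropouts),
* optional second-eye, head-coil (noise-only) and pupil channels,
* an optional slow per-trial "electronic" calibration drift.

All randomness is driven by ``numpy.random.default_rng([seed, trial_index])``
so the same inputs always give bit-identical trials.

Three named presets (``monkey_A``, ``monkey_M``, ``monkey_N``) encode the
per-animal drift-response parameters; everything the presets do not pin down
uses documented defaults chosen for realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

MIN_ARC_PER_DEG = 60.0

#: spatial frequencies (cycles/deg) offered by the grating conditions
SPATIAL_FREQUENCIES = (0.55, 1.1, 2.2, 4.2, 6.8)
#: grating orientations, degrees clockwise from vertical
ORIENTATIONS = (0, 45, 90, 135)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseParams:
    """Stimulus-locked velocity pulse of the drift response.

    The vertical kernel is a trapezoid of height ``peak`` with raised-cosine
    on/off ramps of width ``ramp``, starting at ``t0`` and spanning
    ``duration`` ms in total.  An optional downward dip of amplitude
    ``dip_amp`` and width ``dip_dur`` immediately precedes ``t0`` (seen in
    one animal).  The horizontal channel is a scaled copy of the trapezoid
    with signed amplitude ``h_tilt`` (positive = rightward, i.e. darkness on
    the right).
    """

    t0: float = 80.0          # onset latency, ms post-stimulus
    duration: float = 60.0    # total pulse width, ms
    peak: float = 45.0        # plateau velocity, min arc/s (positive = up)
    ramp: float = 10.0        # cosine ramp width, ms
    h_tilt: float = 0.0       # signed horizontal plateau velocity, min arc/s
    dip_amp: float = 0.0      # initial downward dip amplitude, min arc/s
    dip_dur: float = 0.0      # dip width, ms

    def __post_init__(self) -> None:
        if not (self.ramp > 0 and self.duration >= 2 * self.ramp):
            raise ValueError("pulse requires duration >= 2*ramp > 0")
        if self.peak < 0 or self.t0 < 0:
            raise ValueError("pulse requires peak >= 0 and t0 >= 0")
        if self.dip_amp < 0 or self.dip_dur < 0:
            raise ValueError("dip parameters must be non-negative")

    def displacement(self) -> float:
        """Closed-form time integral of the vertical kernel, in min arc.

        The raised-cosine ramps integrate to ``peak*ramp/2`` each, so the
        trapezoid contributes ``peak*(duration-ramp)`` (ms·min arc/s); the
        sin^2 dip contributes ``-dip_amp*dip_dur/2``.
        """
        trap = self.peak * (self.duration - self.ramp) / 1000.0
        dip = -self.dip_amp * self.dip_dur / 2000.0
        return trap + dip


@dataclass(frozen=True)
class MicrosaccadeParams:
    """Inhomogeneous microsaccade process and movement kinematics."""

    rate: float = 1.5          # baseline rate, /s
    depth: float = 0.95        # inhibition depth (fraction of baseline removed)
    trough: float = 100.0      # time of deepest inhibition, ms post-stimulus
    recovery: float = 350.0    # time at which the rate is back to baseline, ms
    amp_median: float = 12.0   # lognormal amplitude median, min arc
    amp_sigma: float = 0.35    # lognormal sigma (log units)
    duration: float = 20.0     # movement duration, ms

    def __post_init__(self) -> None:
        if min(self.rate, self.depth, self.trough, self.recovery,
               self.amp_median, self.amp_sigma, self.duration) < 0:
            raise ValueError("microsaccade parameters must be non-negative")
        if self.depth > 1:
            raise ValueError("inhibition depth must be <= 1")

    @property
    def main_sequence_slope(self) -> float:
        """Peak velocity / amplitude (1/s) implied by the min-jerk waveform."""
        return 1.875 / (self.duration / 1000.0)


@dataclass(frozen=True)
class PupilParams:
    """Stimulus-evoked pupil constriction (arbitrary units)."""

    latency: float = 220.0     # constriction onset, ms post-stimulus
    amplitude: float = 5.0     # asymptotic constriction, a.u.
    tau: float = 150.0         # exponential time constant, ms
    level: float = 100.0       # resting diameter, a.u.
    noise_sd: float = 0.2      # white measurement noise, a.u.


@dataclass(frozen=True)
class SimPreset:
    """Complete description of one simulated animal/session."""

    name: str
    fs: float = 1000.0                         # sampling rate, Hz
    t_start: int = -400                        # trial span, ms (inclusive)
    t_stop: int = 800                          # trial span, ms (exclusive)
    baseline_drift: tuple[float, float] = (0.0, 0.0)   # (x, y) min arc/s
    diffusion: float = 0.5                     # positional diffusion, min arc^2/s
    noise_sd: float = 0.3                      # white position noise SD, min arc
    fixation_sd: float = 6.0                   # trial-to-trial start scatter, min arc
    pulse: PulseParams = field(default_factory=PulseParams)
    msac: MicrosaccadeParams = field(default_factory=MicrosaccadeParams)
    binocular: bool = False
    head_noise_sd: float = 0.05                # head-coil channel noise, a.u.
    pupil: PupilParams = field(default_factory=PupilParams)
    electronic_drift: float = 0.0              # calibration drift, min arc/trial
    blink_rate: float = 0.0                    # blink rate, /s
    blink_duration: float = 100.0              # dropout length, ms
    white_flash_scale: float = 0.75            # peak scale for white flashes
    sf_t0_shift: float = 25.0                  # t0 delay at the highest SF, ms
    sf_peak_drop: float = 0.45                 # fractional peak loss at highest SF

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.t_stop <= self.t_start:
            raise ValueError("invalid sampling rate or trial span")
        for v in (self.diffusion, self.noise_sd, self.fixation_sd,
                  self.head_noise_sd, self.blink_rate, self.blink_duration):
            if v < 0:
                raise ValueError("rates, SDs and durations must be non-negative")

    def time_axis(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_stop, dtype=int)


# ---------------------------------------------------------------------------
# named presets
# ---------------------------------------------------------------------------

_PRESETS: dict[str, SimPreset] = {
    "monkey_A": SimPreset(
        name="monkey_A",
        baseline_drift=(-2.0, -3.0),
        pulse=PulseParams(t0=80.0, duration=60.0, peak=45.0, ramp=10.0, h_tilt=6.0),
        msac=MicrosaccadeParams(recovery=500.0),   # prolonged inhibition
    ),
    "monkey_M": SimPreset(
        name="monkey_M",
        baseline_drift=(0.0, 5.0),                 # slow upward steady-state drift
        pulse=PulseParams(t0=60.0, duration=90.0, peak=40.0, ramp=10.0, h_tilt=4.0),
        msac=MicrosaccadeParams(),
        binocular=True,
    ),
    "monkey_N": SimPreset(
        name="monkey_N",
        baseline_drift=(3.0, -2.0),
        pulse=PulseParams(t0=70.0, duration=100.0, peak=33.0, ramp=10.0,
                          h_tilt=5.0, dip_amp=8.0, dip_dur=15.0),
        msac=MicrosaccadeParams(),
    ),
}


def available_presets() -> tuple[str, ...]:
    return tuple(_PRESETS)


def make_preset(name: str, **overrides) -> SimPreset:
    """Return a fully populated preset by name, optionally overriding fields.

    Raises ``KeyError`` with the list of available presets for unknown names.
    """
    if name not in _PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_PRESETS))}"
        )
    preset = _PRESETS[name]
    if overrides:
        preset = replace(preset, **overrides)
    return preset


# ---------------------------------------------------------------------------
# condition handling
# ---------------------------------------------------------------------------

def pulse_for_condition(preset: SimPreset, condition: str) -> PulseParams | None:
    """Map a condition label to its pulse parameters (None = no stimulus).

    Conditions: ``none`` (sham onset, no transient), ``black_flash``,
    ``white_flash`` (scaled peak; black flashes drive the response harder),
    ``split_left``/``split_right`` (signed horizontal tilt toward the dark
    side), ``sf_<cpd>`` (lower spatial frequency -> earlier and larger
    pulse) and ``ori_<deg>`` (<=20% peak perturbation with orientation).
    """
    base = preset.pulse
    if condition == "none":
        return None
    if condition == "black_flash":
        return base
    if condition == "white_flash":
        return replace(base, peak=base.peak * preset.white_flash_scale,
                       dip_amp=base.dip_amp * preset.white_flash_scale)
    if condition == "split_right":
        return replace(base, h_tilt=abs(base.h_tilt))
    if condition == "split_left":
        return replace(base, h_tilt=-abs(base.h_tilt))
    if condition.startswith("sf_"):
        sf = float(condition[3:])
        lo, hi = SPATIAL_FREQUENCIES[0], SPATIAL_FREQUENCIES[-1]
        if not lo <= sf <= hi:
            raise KeyError(f"spatial frequency {sf} outside {lo}-{hi} cpd")
        f = np.log(sf / lo) / np.log(hi / lo)      # 0 at lowest, 1 at highest
        return replace(base, t0=base.t0 + preset.sf_t0_shift * f,
                       peak=base.peak * (1.0 - preset.sf_peak_drop * f))
    if condition.startswith("ori_"):
        theta = np.deg2rad(float(condition[4:]))
        return replace(base, peak=base.peak * (1.0 - 0.2 * np.sin(theta) ** 2))
    raise KeyError(f"unknown condition {condition!r} for preset {preset.name!r}")


def pulse_velocity(t_ms: np.ndarray, p: PulseParams) -> tuple[np.ndarray, np.ndarray]:
    """Vertical and horizontal pulse velocity (min arc/s) on a ms grid.

    Zero before ``t0`` except for the optional dip; the vertical kernel is a
    cosine-ramped trapezoid of height ``peak`` between ``t0`` and
    ``t0+duration`` whose integral equals ``PulseParams.displacement()``.
    """
    t = np.asarray(t_ms, dtype=float)
    if t.ndim != 1:
        raise ValueError("time grid must be one-dimensional")
    shape = np.zeros_like(t)
    tau = t - p.t0
    rising = (tau >= 0) & (tau < p.ramp)
    plateau = (tau >= p.ramp) & (tau <= p.duration - p.ramp)
    falling = (tau > p.duration - p.ramp) & (tau <= p.duration)
    shape[rising] = np.sin(0.5 * np.pi * tau[rising] / p.ramp) ** 2
    shape[plateau] = 1.0
    shape[falling] = np.sin(0.5 * np.pi * (p.duration - tau[falling]) / p.ramp) ** 2

    vy = p.peak * shape
    if p.dip_amp > 0 and p.dip_dur > 0:
        ds = t - (p.t0 - p.dip_dur)
        in_dip = (ds >= 0) & (ds <= p.dip_dur)
        vy = vy - p.dip_amp * np.where(in_dip, np.sin(np.pi * ds / p.dip_dur) ** 2, 0.0)
    vx = p.h_tilt * shape
    return vy, vx


def microsaccade_rate_profile(t_ms: np.ndarray, preset: SimPreset,
                              stimulus: bool = True) -> np.ndarray:
    """Instantaneous microsaccade rate (/s) on a ms grid.

    Baseline before 0; for stimulus conditions a multiplicative dip reaches
    ``(1-depth)*baseline`` at the trough time (sin^2 decline) and recovers
    smoothly (cos^2) to baseline by the recovery time.  Never negative.
    """
    t = np.asarray(t_ms, dtype=float)
    m = preset.msac
    rate = np.full(t.shape, m.rate)
    if not stimulus or m.depth == 0:
        return rate
    g = np.zeros_like(t)
    declining = (t >= 0) & (t < m.trough)
    g[declining] = np.sin(0.5 * np.pi * t[declining] / m.trough) ** 2
    recovering = (t >= m.trough) & (t < m.recovery)
    g[recovering] = np.cos(
        0.5 * np.pi * (t[recovering] - m.trough) / (m.recovery - m.trough)) ** 2
    return np.clip(m.rate * (1.0 - m.depth * g), 0.0, None)


# ---------------------------------------------------------------------------
# trial containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthEvent:
    """One injected microsaccade or blink (simulation bookkeeping)."""

    kind: str              # "microsaccade" | "blink"
    onset: float           # ms
    offset: float          # ms
    amplitude: float       # min arc (0 for blinks)
    direction: float       # deg, 0 = rightward, CCW positive


@dataclass
class Trial:
    """One fixation trial: multichannel 1 kHz time series plus metadata.

    Positions are stored in degrees (positive y = up); time is integer ms
    with 0 at (sham) stimulus onset.  ``x2``/``y2`` hold the second eye for
    binocular presets; head channels are unitless; pupil is in a.u.
    ``events`` is the ground-truth injection log (simulation only).
    """

    trial_id: int
    condition: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    x2: np.ndarray | None = None
    y2: np.ndarray | None = None
    head_a: np.ndarray | None = None
    head_b: np.ndarray | None = None
    pupil: np.ndarray | None = None
    events: list[GroundTruthEvent] = field(default_factory=list)
    preset: str = ""
    seed: int = 0

    @property
    def fs(self) -> float:
        return 1000.0 / float(self.t[1] - self.t[0])

    def index_of(self, t_ms: float) -> int:
        i = int(round(t_ms - self.t[0]))
        if not 0 <= i < self.t.size:
            raise ValueError(f"time {t_ms} ms outside trial span "
                             f"[{self.t[0]}, {self.t[-1]}] ms")
        return i


def _minimum_jerk_displacement(n: int) -> np.ndarray:
    """Normalized min-jerk position profile s(tau), s(0)=0, s(1)=1."""
    tau = np.linspace(0.0, 1.0, n)
    return tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)


def _draw_event_times(rng: np.random.Generator, preset: SimPreset,
                      stimulus: bool, lo: float, hi: float) -> np.ndarray:
    """Inhomogeneous-Poisson event onsets in [lo, hi] ms via thinning."""
    m = preset.msac
    if m.rate == 0 or hi <= lo:
        return np.empty(0)
    span_s = (hi - lo) / 1000.0
    n = rng.poisson(m.rate * span_s)
    cand = np.sort(rng.uniform(lo, hi, size=n))
    accept = rng.uniform(size=n) * m.rate <= microsaccade_rate_profile(
        cand, preset, stimulus=stimulus)
    return cand[accept]


def simulate_trial(preset: SimPreset, condition: str, seed: int,
                   trial_index: int = 0) -> Trial:
    """Simulate one trial; identical arguments give bit-identical output."""
    pulse = pulse_for_condition(preset, condition)   # raises for unknown labels
    t = preset.time_axis()
    n = t.size
    dt = 1.0 / preset.fs
    rng = np.random.default_rng([seed & 0x7FFFFFFF, trial_index])

    # shared (binocular) eye-in-head trajectory, min arc
    start = rng.normal(0.0, preset.fixation_sd, size=2)
    bx, by = preset.baseline_drift
    base_x = start[0] + bx * (t - t[0]) / 1000.0
    base_y = start[1] + by * (t - t[0]) / 1000.0
    step_sd = np.sqrt(2.0 * preset.diffusion * dt)
    walk = np.cumsum(rng.normal(0.0, step_sd, size=(2, n)), axis=1)

    if pulse is not None:
        vy, vx = pulse_velocity(t, pulse)
        pulse_x = np.cumsum(vx) * dt
        pulse_y = np.cumsum(vy) * dt
    else:
        pulse_x = pulse_y = np.zeros(n)

    events: list[GroundTruthEvent] = []
    sac_x = np.zeros(n)
    sac_y = np.zeros(n)
    m = preset.msac
    wave_n = int(round(m.duration)) + 1
    margin = 30.0
    onsets = _draw_event_times(rng, preset, pulse is not None,
                               t[0] + margin, t[-1] - m.duration - margin)
    profile = _minimum_jerk_displacement(wave_n)
    for onset in onsets:
        amp = rng.lognormal(np.log(m.amp_median), m.amp_sigma)
        direction = rng.uniform(0.0, 360.0)
        i0 = int(round(onset - t[0]))
        dxy = amp * np.array([np.cos(np.deg2rad(direction)),
                              np.sin(np.deg2rad(direction))])
        sac_x[i0:i0 + wave_n] += dxy[0] * profile
        sac_x[i0 + wave_n:] += dxy[0]
        sac_y[i0:i0 + wave_n] += dxy[1] * profile
        sac_y[i0 + wave_n:] += dxy[1]
        events.append(GroundTruthEvent("microsaccade", float(t[0] + i0),
                                       float(t[0] + i0 + wave_n - 1),
                                       float(amp), float(direction)))

    elec = preset.electronic_drift * trial_index
    true_x = base_x + walk[0] + pulse_x + sac_x + elec
    true_y = base_y + walk[1] + pulse_y + sac_y + elec

    def observe(arr: np.ndarray) -> np.ndarray:
        noisy = arr + rng.normal(0.0, preset.noise_sd, size=n)
        return noisy / MIN_ARC_PER_DEG        # store degrees

    x = observe(true_x)
    y = observe(true_y)
    x2 = y2 = None
    if preset.binocular:
        x2 = observe(true_x)
        y2 = observe(true_y)

    # blinks: coil signal dropout (NaN), recorded in the log
    if preset.blink_rate > 0:
        n_blinks = rng.poisson(preset.blink_rate * n * dt)
        for _ in range(n_blinks):
            b0 = rng.uniform(t[0], t[-1] - preset.blink_duration)
            i0 = int(round(b0 - t[0]))
            i1 = min(n, i0 + int(round(preset.blink_duration)))
            for arr in (x, y) + ((x2, y2) if preset.binocular else ()):
                arr[i0:i1] = np.nan
            events.append(GroundTruthEvent("blink", float(t[0] + i0),
                                           float(t[0] + i1 - 1), 0.0, 0.0))

    head_a = rng.normal(0.0, preset.head_noise_sd, size=n)
    head_b = rng.normal(0.0, preset.head_noise_sd, size=n)

    pp = preset.pupil
    pupil = np.full(n, pp.level) + rng.normal(0.0, pp.noise_sd, size=n)
    if pulse is not None and pp.amplitude != 0:
        late = t >= pp.latency
        pupil[late] -= pp.amplitude * (1.0 - np.exp(-(t[late] - pp.latency) / pp.tau))

    events.sort(key=lambda e: e.onset)
    return Trial(trial_id=trial_index, condition=condition, t=t, x=x, y=y,
                 x2=x2, y2=y2, head_a=head_a, head_b=head_b, pupil=pupil,
                 events=events, preset=preset.name, seed=seed)


def simulate_experiment(preset: SimPreset, n_per_condition: int,
                        conditions: Sequence[str], seed: int):
    """Simulate ``n_per_condition`` independent trials per condition.

    Trials get unique sequential ids and per-trial derived seeds; the
    returned object is a :class:`driftpulse.io.TrialSet`.
    """
    from .io import TrialSet

    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    trials = []
    idx = 0
    for condition in conditions:
        for _ in range(n_per_condition):
            trials.append(simulate_trial(preset, condition, seed, trial_index=idx))
            idx += 1
    return TrialSet(trials=trials, fs=preset.fs,
                    provenance={"preset": preset.name, "seed": int(seed)})
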