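# Methods

## Scope

`driftpulse` has two halves that validate each other: a generative model of
fixational eye-movement recordings around a brief visual transient, and the
event-locked analysis pipeline that recovers the stimulus-driven drift
response from such recordings. Because the generator injects a known pulse,
known microsaccades and known artifacts, every analysis stage is tested by
parameter recovery rather than by eyeballing.

## Generative model

Each trial spans −400…+800 ms around a (sham) stimulus onset at 1 kHz.
Eye position (stored in degrees; reported in min arc, 1/60 deg; positive y
is upward) is the sum of:

* **Steady-state drift** — a constant per-animal velocity vector
  (e.g. (−2, −3) min arc/s for `monkey_A`, (0, +5) for `monkey_M`), plus a
  positional random walk with diffusion coefficient *D* (default
  0.5 min arc²/s). *D* was chosen so that the single-trial smoothed-velocity
  noise stays in the upper part of the 6–10 min arc/s band that matches
  visible trial-to-trial velocity noise in coil recordings; a positional
  random walk has white velocity, so literature-scale diffusion constants
  (tens of min arc²/s) would imply implausibly large instantaneous velocity
  noise at 1 kHz. Trial starting positions scatter with SD 6 min arc.

* **The drift response** — a vertical velocity pulse: a trapezoid of height
  `peak` with raised-cosine ramps of width `ramp`, starting `t0` ms after
  stimulus onset and lasting `duration` ms in total. Its time integral has
  the closed form `peak·(duration−ramp)` (the two half-cosine ramps
  integrate to one ramp's worth of plateau), which the tests use as a
  displacement oracle. A signed, scaled copy of the trapezoid feeds the
  horizontal channel (`h_tilt`, the bias toward the dark half-field for
  split-view stimuli), and an optional preceding downward dip (sin² bump of
  amplitude `dip_amp`, width `dip_dur`) reproduces the brief initial
  downward deflection seen in one animal. Presets:

  | preset | t0 (ms) | duration (ms) | peak (min arc/s) | extras |
  |---|---|---|---|---|
  | monkey_A | 80 | 60 | 45 | prolonged inhibition recovery (500 ms) |
  | monkey_M | 60 | 90 | 40 | binocular |
  | monkey_N | 70 | 100 | 33 | initial dip 8 min arc/s × 15 ms |

  Condition labels modulate the pulse: white flashes scale the peak by 0.75
  (dark transients drive the response harder), `split_left/right` set the
  horizontal tilt sign, spatial-frequency conditions delay `t0` by up to
  25 ms and shrink the peak by up to 45% monotonically from 0.55 to
  6.8 cpd, and orientation conditions perturb the peak by ≤ 20%.

* **Microsaccades** — an inhomogeneous point process: baseline rate 1.5/s,
  multiplicatively suppressed after stimulus onset (sin² decline reaching
  depth 0.95 at the 100-ms trough, cos² recovery to baseline by 350 ms;
  500 ms for `monkey_A`). The trough time is set so that every preset's
  drift-response onset falls where the measured rate curve is below 50% of
  baseline, mirroring the observed timing relation between the drift
  response and saccadic inhibition. Amplitudes are lognormal (median
  12 min arc, σ = 0.35 log units); waveforms are minimum-jerk with a fixed
  20-ms duration, which pins the main-sequence slope at
  1.875/0.020 s ≈ 94 (peak velocity per unit amplitude) — a duration and a
  slope cannot be chosen independently for a fixed waveform shape, and the
  duration is the physiologically standard quantity. Directions are
  uniform: the generator injects no post-response direction bias, which is
  itself a tested null.

* **Measurement layer** — white position noise (SD 0.3 min arc per sample
  per channel); binocular presets give the second eye the same drift,
  pulse and microsaccades with independent noise (so vergence is null by
  construction); two noise-only head-coil channels (arbitrary units);
  a pupil channel that constricts after stimulus onset (220-ms latency,
  exponential approach with 150-ms time constant, arbitrary units — only
  the sign and the onset ordering relative to the drift response are ever
  interpreted); optional blink dropouts (NaN runs); and an optional linear
  "electronic" calibration drift per trial.

All randomness derives from `default_rng([seed, trial_index])`: identical
arguments give bit-identical trials, and experiments are embarrassingly
reproducible.

### What the generator does not emulate

Real coil data have 1/f-ish drift spectra, amplitude–duration covariation
in microsaccades, session-level nonstationarity, and genuinely
stimulus-dependent pupil and microsaccade-direction dynamics. Passing the
recovery tests therefore shows that the *pipeline* is correct and
well-calibrated under realistic noise magnitudes — not that every modeling
assumption holds in real recordings. The analysis code makes none of the
generator's assumptions beyond uniform sampling.

## Analysis pipeline

**Velocity.** Symmetric Savitzky–Golay differentiator, polynomial order 2,
21-sample window at 1 kHz (configurable; results should be stable over
11–31 ms windows). It is linear, shift-equivariant, exact on quadratics,
and blurs onsets by up to half a window both backwards and forwards —
which is why recovered onsets sit ~2–3 ms early and durations run ~5 ms
long relative to injected values. Filter edges are invalid.

**Event detection.** Engbert–Kliegl velocity threshold: per-component
median-based scale σ = √(median(v²) − median(v)²), elliptic criterion with
λ = 6, minimum duration 6 ms, merge gap 20 ms; events below 1 deg amplitude
are microsaccades. Two additions: (i) a 3 deg/s peak-velocity floor —
the median-based scale is ≈ 0.67 of a Gaussian SD, so with λ = 6 the
effective threshold (~0.9 deg/s here) sits close to the drift-response
plateau (0.75 deg/s), and without the floor the response itself would be
flagged as saccadic in a large fraction of stimulus trials, biasing the
ensemble; microsaccades in this noise regime always exceed 5 deg/s.
(ii) onset/offset refinement to the crossing of 25% of each event's own
peak velocity (never below the detection threshold), which undoes the
smoothing filter's spread of threshold crossings; localization on
noise-free fixtures is then exact. Blinks are NaN dropouts or > 20 deg
excursions, padded ± 50 ms.

**Epoch selection.** Trials with any saccade/microsaccade/blink
overlapping −100…+200 ms are excluded (the window is configurable and can
be extended to +350 ms in 50-ms steps). A sanity check rejects any trial
whose saccade-free smoothed speed exceeds 3 deg/s (1-ms electronic
artifacts); detected-event masks are padded by the filter half-window.

**Bands and divergence.** Aligned ensembles carry per-sample validity
masks (events, blinks, filter edges) honored by all averages; per-ms means
with fewer than 10 valid trials are flagged undefined, never plotted or
compared. 95% confidence bands are parametric *t* intervals by default,
with a percentile bootstrap (1000 resamples) as an option — the two agree
on all presets. Non-overlap runs shorter than 20 ms are reported but not
significant. Onset search is restricted to *t* ≥ 0; pre-stimulus
divergences are anomalies, not onsets. The response offset requires the
re-overlap to persist ≥ 20 ms (symmetric to the onset rule); equal peaks
tie-break to the earliest time.

**Peak velocity.** `characterize_response` reports the peak of the
control-subtracted mean vertical velocity in the search window
(50–140 ms for flashes, 80–140 ms for gratings): subtracting the control
band removes the animal's steady-state drift so the number estimates the
response itself, and recovers the injected plateau. Per-trial peaks feed
the rank-based condition comparisons (Wilcoxon rank-sum for two groups;
Kruskal–Wallis with Bonferroni-corrected pairwise post-hocs for more).
No correction is applied across the onset and peak analyses.

**Rate curves.** Event onsets counted in an 80-ms window centered on each
5-ms step from −300 to +600 ms, normalized to movements/s (a trailing
window is available; only trough-relative statements are made, which are
robust to the choice). Inhibition parameters are recovered by
least-squares fitting the *window-averaged* parametric profile to the
measured curve: the raw curve minimum is biased late by the asymmetry
between the fast decline and the slow recovery limbs under an 80-ms window,
and fitting the smeared model rather than reading off the argmin removes
that bias.

**Hinge onsets.** The piecewise-linear (two-segment continuous) latency
fit scans breakpoints on a 1-ms grid and keeps the least-squares optimum.
Only samples from 100 ms before the search window to its end enter the
fit: the hinge is a local model of the onset region, and including the
trace's late curvature (e.g. the saturating pupil constriction) drags the
breakpoint early. With the default span the recovered pupil onset is
within ~15 ms of the injected 220-ms latency; only its ordering relative
to the drift-response onset is asserted.

**Controls.** Median split on mean vertical position over the final 50 ms
before onset (ties below); paired-interval rank-sum tests compare mean
channel velocity in −100…0 ms vs 50…150 ms for vergence (left − right,
positive = convergence), head channels (differentiated with the same
filter as eye velocity) and the eye itself; electronic drift is the linear
slope of the 30-ms pre-stimulus mean position against session time
(default 5 s/trial spacing) and is flagged unless at least ten-fold slower
than the physiological baseline drift speed (median per-trial pre-stimulus
velocity magnitude).

## Statistical calibration of the tests themselves

Null-hypothesis contracts ("vergence is not significant") are enforced at
the replicate level: an exactly calibrated α = 0.05 test flags 5% of null
sessions, so the suite asserts false-positive rates within a 3-SD binomial
allowance of nominal over ≥ 200 simulated experiments, and single fixture
runs only assert that null p-values are unexceptional (> 10⁻³) while true
effects are overwhelming (< 10⁻¹⁰). The CI-divergence false-positive rate
(any spurious ≥ 20-ms run in 0–200 ms on control-vs-control splits at
200 trials/side) measures ≤ 10%.

## Problem sizes

Recovery experiments use 400 stimulus + 400 control trials per preset
(~150–330 trials per real session, pooled across sessions, is typical for
this kind of data); replicate-based rate checks use 200 experiments of
60–400 trials. The full suite runs in under a minute on one CPU; the
acceptance script in a few seconds.

## Known limitations

* Onset/duration estimates inherit the differentiator's temporal blur
  (~±half a window); the 20-ms persistence rule further quantizes offsets.
* The hinge fit is biased early on saturating traces; the restricted fit
  span mitigates but does not remove this.
* The divergence rule is a fixed-threshold procedure, not a cluster-based
  permutation test; its false-positive rate is verified empirically rather
  than controlled analytically.
* Binocular coupling is perfect by construction; real data show small
  genuine interocular differences.
* Head channels are modeled as pure noise in arbitrary units; only
  stimulus-locked change is ever tested, not calibrated head kinematics.
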