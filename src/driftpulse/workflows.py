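"""End-to-end analysis workflows built from the library modules.

`drift_response_experiment` is the canonical pipeline: simulate (or accept)
a set of stimulus and control trials, detect events, keep saccade-free
epochs, run the velocity-outlier sanity check, align, and characterize the
stimulus-vs-control drift response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import DetectionParams, detect_all, filter_saccade_free, \
    velocity_outlier_check
from .io import TrialSet
from .kinematics import AlignedEnsemble, align_positions
from .response import DriftResponseEstimate, characterize_response
from .simulate import SimPreset, make_preset, simulate_experiment


@dataclass
class ExperimentResult:
    estimate: DriftResponseEstimate
    stim_ensemble: AlignedEnsemble
    ctrl_ensemble: AlignedEnsemble
    stim_set: TrialSet
    ctrl_set: TrialSet
    events: dict
    report: object = None


def prepare_ensembles(ts: TrialSet, stim_condition: str,
                      ctrl_condition: str = "none",
                      sf_window: tuple[float, float] = (-100.0, 200.0),
                      outlier_ceiling: float = 3.0,
                      detection: DetectionParams = DetectionParams()
                      ) -> ExperimentResult:
    """Event detection, saccade-free filtering, outlier check and alignment."""
    events = {tr.trial_id: detect_all(tr, detection) for tr in ts}
    kept, report = filter_saccade_free(ts, window=sf_window, events=events)
    kept = TrialSet([tr for tr in kept
                     if velocity_outlier_check(tr, ceiling=outlier_ceiling,
                                               events=events[tr.trial_id],
                                               params=detection)],
                    fs=ts.fs, provenance=dict(ts.provenance))
    stim_set = kept.select(stim_condition)
    ctrl_set = kept.select(ctrl_condition)
    stim_ens = align_positions(stim_set, events=events)
    ctrl_ens = align_positions(ctrl_set, events=events)
    return ExperimentResult(estimate=None, stim_ensemble=stim_ens,
                            ctrl_ensemble=ctrl_ens, stim_set=stim_set,
                            ctrl_set=ctrl_set, events=events, report=report)


def drift_response_experiment(preset: str | SimPreset = "monkey_A",
                              condition: str = "black_flash",
                              n_per_condition: int = 400, seed: int = 1,
                              sf_window: tuple[float, float] = (-100.0, 200.0),
                              peak_window: tuple[float, float] = (50.0, 140.0),
                              disp_window: tuple[float, float] = (150.0, 200.0),
                              min_run: float = 20.0,
                              ci_method: str = "t") -> ExperimentResult:
    """Simulate and analyze one stimulus-vs-control experiment."""
    if isinstance(preset, str):
        preset = make_preset(preset)
    ts = simulate_experiment(preset, n_per_condition, [condition, "none"], seed)
    res = prepare_ensembles(ts, condition, sf_window=sf_window)
    res.estimate = characterize_response(
        res.stim_ensemble, res.ctrl_ensemble, peak_window=peak_window,
        disp_window=disp_window, min_run=min_run, ci_method=ci_method,
        condition=condition)
    return res
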