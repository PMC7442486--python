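"""Tabular trial I/O and validation.

Trials travel as three CSV files (comma-separated, UTF-8, header row,
'.' decimal):

* ``samples.csv`` — trial_id, t_ms, x_deg, y_deg and, when present,
  x2_deg, y2_deg, head_a, head_b, pupil.  Positions are degrees
  (1 min arc = 1/60 deg, positive y = up); time is integer ms with 0 at the
  (sham) stimulus onset, so stimulus and control trials run through
  identical code paths.
* ``trials.csv`` — trial_id, condition, preset, seed.
* ``events.csv`` (optional) — ground-truth injection log:
  trial_id, kind, onset_ms, offset_ms, amplitude_minarc, direction_deg.

Floats are written with 12 significant digits, enough for a bit-stable
round trip at 1e-9 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .simulate import GroundTruthEvent, Trial

_OPTIONAL_CHANNELS = {
    "x2_deg": "x2", "y2_deg": "y2",
    "head_a": "head_a", "head_b": "head_b", "pupil": "pupil",
}
_FLOAT_FORMAT = "%.12g"


@dataclass
class TrialSet:
    """An ordered collection of trials sharing sampling rate and time span."""

    trials: list[Trial]
    fs: float = 1000.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [tr.trial_id for tr in self.trials]
        if len(set(ids)) != len(ids):
            raise ValueError("trial_ids must be unique")
        if self.trials:
            t0 = self.trials[0].t
            for tr in self.trials[1:]:
                if tr.t.size != t0.size or tr.t[0] != t0[0]:
                    raise ValueError("all trials must share one time axis")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __getitem__(self, i: int) -> Trial:
        return self.trials[i]

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for tr in self.trials:
            seen.setdefault(tr.condition, None)
        return tuple(seen)

    @property
    def channels(self) -> tuple[str, ...]:
        if not self.trials:
            return ("x", "y")
        tr = self.trials[0]
        out = ["x", "y"]
        for name in ("x2", "y2", "head_a", "head_b", "pupil"):
            if getattr(tr, name) is not None:
                out.append(name)
        return tuple(out)

    def select(self, condition: str) -> "TrialSet":
        return TrialSet([tr for tr in self.trials if tr.condition == condition],
                        fs=self.fs, provenance=dict(self.provenance))

    def validate_span(self, window: tuple[float, float] = (-300, 600)) -> None:
        """Reject trials shorter than the configured analysis span."""
        for tr in self.trials:
            if tr.t[0] > window[0] or tr.t[-1] < window[1]:
                raise ValueError(
                    f"trial {tr.trial_id} spans [{tr.t[0]}, {tr.t[-1]}] ms, "
                    f"shorter than the analysis span {window}")


def write_trials(ts: TrialSet, out_dir: str | Path) -> dict[str, Path]:
    """Write samples/trials/events CSVs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    frames = []
    for tr in ts:
        cols = {"trial_id": tr.trial_id, "t_ms": tr.t,
                "x_deg": tr.x, "y_deg": tr.y}
        for col, attr in _OPTIONAL_CHANNELS.items():
            val = getattr(tr, attr)
            if val is not None:
                cols[col] = val
        frames.append(pd.DataFrame(cols))
    samples = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["trial_id", "t_ms", "x_deg", "y_deg"])

    meta = pd.DataFrame({
        "trial_id": [tr.trial_id for tr in ts],
        "condition": [tr.condition for tr in ts],
        "preset": [tr.preset for tr in ts],
        "seed": [tr.seed for tr in ts],
    })
    ev_rows = [
        {"trial_id": tr.trial_id, "kind": e.kind, "onset_ms": e.onset,
         "offset_ms": e.offset, "amplitude_minarc": e.amplitude,
         "direction_deg": e.direction}
        for tr in ts for e in tr.events
    ]
    events = pd.DataFrame(ev_rows, columns=["trial_id", "kind", "onset_ms",
                                            "offset_ms", "amplitude_minarc",
                                            "direction_deg"])

    paths = {"samples": out / "samples.csv", "trials": out / "trials.csv",
             "events": out / "events.csv"}
    samples.to_csv(paths["samples"], index=False, float_format=_FLOAT_FORMAT)
    meta.to_csv(paths["trials"], index=False)
    events.to_csv(paths["events"], index=False, float_format=_FLOAT_FORMAT)
    return paths


def read_trials(samples_path: str | Path, trials_path: str | Path,
                events_path: str | Path | None = None) -> TrialSet:
    """Read and validate a TrialSet written by :func:`write_trials`.

    Rejects empty inputs, duplicate (trial_id, t_ms) rows, non-uniform time
    axes and mixed sampling rates with descriptive errors.
    """
    samples = pd.read_csv(samples_path)
    if samples.empty:
        raise ValueError(f"no trials in {samples_path}")
    required = {"trial_id", "t_ms", "x_deg", "y_deg"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples file missing columns: {sorted(missing)}")
    meta = pd.read_csv(trials_path).set_index("trial_id")

    events_by_trial: dict[int, list[GroundTruthEvent]] = {}
    if events_path is not None and Path(events_path).exists():
        for row in pd.read_csv(events_path).itertuples():
            events_by_trial.setdefault(int(row.trial_id), []).append(
                GroundTruthEvent(row.kind, float(row.onset_ms),
                                 float(row.offset_ms),
                                 float(row.amplitude_minarc),
                                 float(row.direction_deg)))

    trials: list[Trial] = []
    step = None
    for trial_id, grp in samples.groupby("trial_id", sort=False):
        t = grp["t_ms"].to_numpy()
        if np.unique(t).size != t.size:
            raise ValueError(f"duplicate (trial_id, t_ms) rows in trial {trial_id}")
        dt = np.diff(t)
        if t.size < 2 or not np.all(dt == dt[0]):
            raise ValueError(f"non-uniform time axis in trial {trial_id}")
        if step is None:
            step = dt[0]
        elif dt[0] != step:
            raise ValueError("mixed sampling rates across trials")
        try:
            mrow = meta.loc[int(trial_id)]
        except KeyError:
            raise ValueError(f"trial {trial_id} missing from trials file") from None

        def chan(col: str) -> np.ndarray | None:
            return grp[col].to_numpy() if col in grp.columns else None

        trials.append(Trial(
            trial_id=int(trial_id), condition=str(mrow["condition"]),
            t=t.astype(int), x=grp["x_deg"].to_numpy(), y=grp["y_deg"].to_numpy(),
            x2=chan("x2_deg"), y2=chan("y2_deg"),
            head_a=chan("head_a"), head_b=chan("head_b"), pupil=chan("pupil"),
            events=events_by_trial.get(int(trial_id), []),
            preset=str(mrow.get("preset", "")), seed=int(mrow.get("seed", 0))))

    fs = 1000.0 / float(step)
    return TrialSet(trials=trials, fs=fs,
                    provenance={"samples": str(samples_path),
                                "trials": str(trials_path)})
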