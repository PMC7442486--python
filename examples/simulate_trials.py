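"""Generate a synthetic fixation session and write it to CSV files.

Each trial is a 1 kHz two-channel (or binocular four-channel) position
recording spanning -400..+800 ms around a (sham) stimulus onset, with
head-coil and pupil channels and a ground-truth log of every injected
microsaccade.
"""

import pathlib

import driftpulse as dp

preset = dp.make_preset("monkey_M")           # binocular animal
ts = dp.simulate_experiment(preset, n_per_condition=50,
                            conditions=["black_flash", "none"], seed=7)
out = pathlib.Path("scratch/example_session")
paths = dp.write_trials(ts, out)

n_msacs = sum(1 for tr in ts for e in tr.events if e.kind == "microsaccade")
print(f"wrote {len(ts)} trials ({', '.join(ts.channels)} channels) to {out}/")
print(f"ground-truth microsaccades injected: {n_msacs}")
print(f"files: {', '.join(p.name for p in paths.values())}")

back = dp.read_trials(paths["samples"], paths["trials"], paths["events"])
print(f"round trip: {len(back)} trials at {back.fs:.0f} Hz, "
      f"conditions {back.conditions}")
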