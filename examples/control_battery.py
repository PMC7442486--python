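"""Artifact controls: vergence, head movement, pupil latency, electronic drift.

A genuine drift response is a binocular eye rotation: both eyes show the
vertical velocity change, the vergence (left-right) channel does not, the
head-coil channels stay at noise level, the pupil constricts only later,
and any electronic calibration drift is orders of magnitude slower than
physiological drift.
"""

import driftpulse as dp
from driftpulse.controls import (electronic_drift_speed, head_movement_check,
                                 pupil_response, vergence_check)
from driftpulse.events import filter_saccade_free

ts = dp.simulate_experiment(dp.make_preset("monkey_M"), 200,
                            ["black_flash"], seed=12)
kept, _ = filter_saccade_free(ts, window=(-100, 200))

verg = vergence_check(kept)
print(f"vertical response  : p = {verg.eye1_vertical.p_value:.2e} (right eye), "
      f"p = {verg.eye2_vertical.p_value:.2e} (left eye)")
print(f"vergence velocity  : p = {verg.vergence.p_value:.3f}  "
      "(null channel; an alpha=0.05 test flags ~1 in 20 sessions by chance)")

head = head_movement_check(kept)
print(f"head channels      : p = {head['head_a'].p_value:.3f} / "
      f"{head['head_b'].p_value:.3f}  (no head movement)")

pup = pupil_response(kept, drift_onset=60.0)
print(f"pupil constriction : onset {pup.onset:.0f} ms "
      f"(later than the 60 ms drift response: {pup.pupil_later})")

ed = electronic_drift_speed(ts, trial_spacing_s=5.0)
print(f"electronic drift   : {ed.speed_minarc_per_s:.4f} min arc/s vs "
      f"physiological {ed.physiological_speed:.2f} min arc/s "
      f"(flagged: {ed.flagged})")
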