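"""Generate beat-discrimination trial sequences and calibrate difficulty.

Builds one trial at a 1.3 Hz tempo, prints its event stream, then runs the
weighted up-down staircase against a synthetic responder to find the
distractor density yielding ~75% correct at the 2 Hz calibration tempo.
"""

import numpy as np

from tempotrack import (
    BeatSpec,
    ObserverParams,
    accuracy_model,
    generate_trial,
    run_staircase,
    validate_sequence,
)

seq = generate_trial(BeatSpec(1.3), density=1.0, deviant_on_beat=False, rng=7)
print(f"trial at {seq.beat.frequency_hz} Hz: {seq.n_targets} targets, "
      f"{seq.n_distractors} distractors, span {seq.duration:.2f} s, "
      f"deviant offset {seq.deviant_offset * 1000:+.0f} ms")
for ev in seq.events[:6]:
    print(f"  {ev.onset:7.3f} s  {ev.role}")
print("  ...")
print("validator violations:", validate_sequence(seq))

# Staircase: the synthetic observer answers correctly with the probability
# given by its accuracy model, so the track should settle where expected
# accuracy crosses 75%.
observer = ObserverParams.auditory_default()
rng = np.random.default_rng(0)
threshold = run_staircase(
    lambda s: bool(rng.random() < accuracy_model(s.beat.frequency_hz, s.density, observer)),
    max_trials=1500, n_reversals=300, rng=1,
)
print(f"\nstaircase threshold density: {threshold:.2f} distractors per beat")
print("(the auditory observer's 75%-correct density at 2 Hz is ~1.0)")
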