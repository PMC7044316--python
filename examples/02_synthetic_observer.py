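"""Simulate a synthetic observer over a full session.

Generates 40 trials per condition on the 8-tempo auditory grid and prints
the per-condition accuracy: an inverse-U over tempo peaking near the
observer's optimal tempo (1.4 Hz by default).
"""

from tempotrack import ObserverParams, accuracy_model, generate_experiment

observer = ObserverParams.auditory_default()
ds = generate_experiment("auditory_8", 40, observer, density=1.0,
                         sessions=("passive",), rng_seed=3, include_taps=False)
print(f"{len(ds.trials)} trials (8 conditions x 40)")
print(f"{'tempo (Hz)':>10} {'observed':>9} {'expected':>9}")
for f, sub in ds.trials.groupby("condition_hz"):
    print(f"{f:>10.1f} {sub.response_correct.mean():>9.3f} "
          f"{accuracy_model(f, 1.0, observer):>9.3f}")
print("\nobserved accuracy tracks the observer's generative inverse-U;")
print("the peak sits near its optimal tempo of "
      f"{observer.optimal_tempo_hz} Hz")
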