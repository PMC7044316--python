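# tempotrack

Tools for studying the rhythmic sampling capacities of periodic temporal
attention: beat-discrimination paradigms, synthetic observers, the standard
behavioural estimators, and a dynamical model of stimulus–attention–motor
coupling.

Who this is for: researchers in auditory/visual psychophysics and
computational neuroscience who need (a) constraint-checked isochronous
stimulus sequences with calibrated distractor load, (b) estimators for
optimal tempo and sensorimotor synchronisation quality, and (c) a
phase-oscillator model that ties the two together — all scriptable from
Python, with a thin CLI for batch use.

## The science in brief

**Paradigm.** A trial is an isochronous stream at beat frequency *f* (the
tempo): three reference stimuli establish the beat, then on-beat targets
interleaved with off-beat distractors (density *d* distractors per beat,
the difficulty knob, calibrated to 75% correct by a weighted up-down
staircase at 2 Hz), terminated by a deviant judged on- vs off-beat.
Performance across tempi traces an inverse U whose peak is the optimal
sampling rate of temporal attention.

**Estimators.** Per-condition performance (or tapping CV) is fitted with a
third-order polynomial f(x) = ax³ + bx² + cx + d; with δ = b² − 3ac > 0 the
local maximum is

    α = (−b − √δ) / (3a)

(and β = (−b + √δ)/(3a) the local minimum). Guided tapping is summarised by
precision (mean tap rate / tempo, %), the coefficient of variation
(SD of inter-tap intervals / beat period), and sensorimotor simultaneity
Φ = 2π·(tap − nearest beat)/T wrapped to (−π, π] — negative Φ is
anticipatory. Model comparison uses the AIC Bayes factor
BF = exp((AIC_null − AIC_effect)/2), with BF < 1/3 read as evidence for the
null.

**Model.** Three phase oscillators — stimulus S (purely periodic),
attention A, motor M — with sine coupling, transmission delays and white
phase noise:

    θ̇_S = 2π ω_S
    θ̇_A = 2π ω_A + K_AM sin[θ_M(t−τ_AM) − θ_A] + K_AS sin[θ_S(t−τ_AS) − θ_A] + ξ_A
    θ̇_M = 2π ω_M + K_MA sin[θ_A(t−τ_MA) − θ_M] + K_MS sin[θ_S(t−τ_MS) − θ_M] + ξ_M

with ⟨ξ_i(t) ξ_j(t′)⟩ = 2D_i δ(t−t′) δ_ij. Behavioural performance is
approximated by the phase-locking value PLV = |⟨e^{i(θ_S−θ_A)}⟩|: sweeping
ω_S across conditions yields an inverse-U PLV curve peaking near ω_A
(1.5 Hz auditory, 0.7 Hz visual). The passive→tracking contrast is a single
parameter (K_AM: 2 → 10); whether stronger motor coupling helps or hurts
entrainment is set by the stimulus-to-motor delay τ_MS (100 ms auditory →
beneficial, 350 ms visual → disruptive).

## Worked example

```python
from tempotrack import condition_set, fit_cubic_optimal_tempo, frequency_sweep, preset

freqs = condition_set("visual_10")            # 0.3 ... 3.8 Hz
p = preset("auditory", "passive", duration=200.0, burn_in=50.0)
curve = frequency_sweep(p, freqs, n_realizations=3, base_seed=1)
fit = fit_cubic_optimal_tempo(curve.stim_freqs_hz, curve.plv_mean)
print(f"PLV peak at {fit.alpha:.2f} Hz")
```

Running `python examples/04_oscillator_model.py` prints:

```
auditory passive: attention natural frequency 1.5 Hz, PLV peak at 1.42 Hz
visual passive: attention natural frequency 0.7 Hz, PLV peak at 0.61 Hz

motor modulation at a 1.7 Hz stimulus (tracking - passive PLV):
  auditory (stimulus->motor delay 100 ms): +0.017 (beneficial motor coupling)
  visual (stimulus->motor delay 350 ms): -0.132 (disruptive motor coupling)
```

The PLV resonance sits close to each modality's attentional natural
frequency, and at a 1.7 Hz stimulus the tracking session raises locking in
the auditory configuration but lowers it in the visual one — the
delay-dependent sign flip of the motor contribution. The other scripts in
`examples/` walk through sequence generation and staircase calibration
(01), the synthetic observer (02), the behavioural estimators (03), and
the end-to-end pipeline with its JSON report (05).

## Command line

```bash
tempotrack generate --modality auditory --preset auditory_8 --density 1.0 \
    --n-trials 40 --seed 42 --out trials.csv
tempotrack simulate-observer --seed 7 --out-dir data/
tempotrack analyze --trials data/trials.csv --taps data/taps.csv --out metrics.json
tempotrack model sweep --modality auditory --session tracking --reps 10 \
    --duration 1000 --seed 1 --out sweep.csv
tempotrack model fit --sweep sweep.csv --curve perf.csv --out fit.json
tempotrack run --config run.json        # exit 0 ok / 2 config error / 3 stage failure
```

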