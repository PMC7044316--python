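# Methods

This note documents the models and procedures implemented in `tempotrack`,
the conventions and defaults they use, and the numerical and design choices
made where more than one reading was defensible.

## 1. Trial sequences (`tempotrack.paradigm`)

A trial at beat period T = 1/f is laid out as: references at 0, T, 2T;
n targets at 3T … (2+n)T; a single terminal deviant one beat after the last
target, displaced by a signed offset when off-beat. Hard constraints,
enforced by the generator and re-checked by `validate_sequence`:

- onsets strictly increasing; every inter-onset interval ≥ 0.09 T (stimuli
  must never overlap or fuse);
- 4 ≤ n ≤ 22 targets (references and deviant excluded); trial span ≥ 2 s;
- off-beat deviant offsets drawn uniformly from ±[0.09 T, T/2]. The lower
  bound mirrors the global inter-onset floor so that off-beat deviants stay
  discriminable in principle; exactly-on-beat "off-beat" trials cannot occur.

Stimulus duration follows the modality rule: 10% of the ISI for tones, 18%
for gratings, or a fixed 22.5 ms in the tempo/duration-orthogonalised
control (`BeatSpec(duration_rule="fixed")`).

**Target count.** n is drawn uniformly over the subset of [4, 22] that
keeps the expected deviant onset inside the nominal duration bounds
(2–12 s auditory, 2–20 s visual). The bounds are soft at the slow end: at
0.3 Hz the 4-target floor alone implies ≈ 23 s, so the floor wins. The
2 s minimum is hard.

**Distractors.** The count is Poisson with mean d·n (d = density,
distractors per beat), so the long-run realised count per beat equals the
requested density exactly. Positions are drawn sequentially, uniformly on
the span from the first target to the deviant, redrawing any draw that
lands within 0.09 T of an already-placed event (1000 draws total per
trial). Sequential placement keeps the per-point law near-uniform while
remaining feasible at realistic densities, where accept-reject over whole
configurations has vanishing acceptance probability. Densities that
genuinely cannot fit raise an infeasibility error naming the binding
constraint rather than silently degrading.

Time is continuous in seconds throughout; onsets are never snapped to a
display or audio frame grid (presentation hardware is out of scope).

## 2. Staircase calibration

Difficulty is calibrated at a fixed 2 Hz tempo with a Kaernbach-style
weighted up-down staircase on density: +s after a correct response
(harder), −3s after an error (easier). The 1:3 ratio makes the stationary
point satisfy p·s = (1−p)·3s, i.e. p = 0.75. Both steps shrink by 0.95 at
each reversal down to a floor (0.03 / 0.09) that preserves the ratio — a
floor that let both steps collapse to equality would silently retarget
50%. Defaults: start at density 0.5, steps 0.1/0.3, 800-trial budget.

The full budget is always run and the threshold is the mean density over
the last k reversals (default 6). A single track wanders with an SD of
roughly 20% of the threshold in our synthetic tests — the accuracy model's
slope against density is shallow — so consumers needing tight estimates
should average several tracks and widen k (the convergence test uses 8
tracks × 300 reversals); the procedure is unbiased in our checks. A track
with zero reversals raises a non-convergence error carrying the full
(density, response) trajectory.

## 3. Synthetic observer (`tempotrack.observer`)

The observer is a statistical emulator, not a process model: it generates
data with the structure the estimators assume, nothing more.

**Responses.** Expected accuracy is a Gaussian bump on the log2-frequency
axis, attenuated linearly by density and mixed with a lapse:

    p(f, d) = (1 − λ)·[0.5 + (p_max − 0.5)·exp(−(log2 f − log2 f*)² / 2w²)
                         ·max(0, 1 − s·d)] + λ/2

Chance is 0.5 (binary on/off-beat judgment). The generative family is
deliberately *not* a cubic: the cubic is the estimator under test, and
recovering its maximum from data generated by a different family keeps
parameter recovery non-circular.

**Taps** (tracking trials) start at the second reference and follow
tap_k = T + k·ITI + A + ε_k, with ITI = T + c·(T − 1/1.7),
ε_k ~ N(0, (σ·T)²). A is the mean asynchrony (negative = anticipatory),
c < 0 reproduces tapping too fast at slow tempi and too slow at fast ones,
pivoting at the ~1.7 Hz spontaneous motor rate. Jitter is independent
across taps (no drift or autoregressive structure) — the simplest model
supporting the CV and Φ definitions. Consequence: the SD of inter-tap
intervals is √2·σ·T, so the CV estimates √2·σ, and away from 1.7 Hz the
rate-compression drift dominates trial-mean Φ.

**Defaults** (chosen once to emulate the study conditions these analyses
assume, and frozen):

| parameter | auditory | visual | meaning |
|---|---|---|---|
| f* | 1.4 Hz | 0.7 Hz | optimal tempo |
| w | 1.0 oct | 1.5 oct | tuning width (log2 axis) |
| p_max | 0.95 | 0.95 | peak accuracy at d = 0 |
| λ | 0.02 | 0.02 | lapse rate |
| s | 0.35 | 0.26 | accuracy loss per unit density |
| σ | 0.05 | 0.08 | tap jitter, fraction of T |
| A | −30 ms | +50 ms | mean asynchrony (anticipatory / reactive) |
| c | −0.2 | −0.2 | rate compression |

The density slopes place the 75%-correct threshold at 2 Hz near density
1.0 (auditory) and 0.28 (visual), the difficulty levels these experiments
typically produce; the asynchrony signs encode anticipatory auditory vs
reactive visual tapping. What the emulator does **not** capture: trial-level
dependence (learning, fatigue), deviant-position effects, any
entrainment-based decision process, and tap-timing autocorrelation. Tests
passing on this generator therefore validate the estimators and pipeline,
not claims about human data.

## 4. Estimators (`tempotrack.metrics`)

**Cubic optimal tempo.** Least squares on the linear Hz axis (the axis on
which these curves are conventionally plotted and reported); log2-axis
fitting is available via `log_axis=True`. α = (−b − √δ)/(3a) with
δ = b² − 3ac; this branch is always the maximum since f″(α) = −2√δ < 0.
δ ≤ 0 or a ≈ 0 (|a| ≤ 1e−12) yields a structured no-optimum signal —
distinct from invalid input, which raises. α outside the data range is
returned but flagged (`alpha_in_range=False`); extrapolated optima should
not be trusted. R² = 1 − SS_res/SS_tot; no p-value is attached (group-level
inference is out of scope). At least 4 distinct frequencies are required.

**Tapping.** Precision = 100·T/mean(ITI) (a frequency ratio); CV =
sample SD (n−1) of ITIs divided by T. These are the two readings of
"ratio to the tempo" that make both quantities dimensionless. Population
vs sample SD is not dictated by convention here; sample SD was chosen and
matters only for very short trials.

**Sensorimotor simultaneity.** Each tap maps to its *nearest* beat (no
exclusivity — several taps may share a beat, since no pairing rule is
canonical); Φ = 2π(tap − beat)/T wrapped to (−π, π]. Trial means are
arithmetic, not circular: values concentrate near 0 by construction, where
the two coincide; a circular mean can be computed from the per-tap phases
exposed on the result. Both signed (anticipatory vs reactive) and absolute
(quality) indexes are returned.

**Median split.** Stable sort on the key; low group takes the first
⌈n/2⌉ rows (odd-count median joins the low group); all-identical keys
raise a degenerate-split error.

**AIC Bayes factor.** BF = exp((AIC_null − AIC_effect)/2), labelled
evidence-for-null below 1/3.

## 5. Oscillator model (`tempotrack.oscillators`)

Equations as in the README. Conventions and numerical choices:

- **Units.** Natural frequencies ω are entered in Hz and multiplied by 2π
  inside the integrator. Coupling strengths K are in rad/s and noise
  intensities D in rad²/s. *Flag:* the alternative reading of K and D in
  units of 2π·Hz is not adopted; with K_AS = 10 rad/s the S→A locking
  half-width is K/2π ≈ 1.6 Hz around ω_A, which is what produces
  inverse-U PLV curves spanning the 0.3–3.8 Hz condition range, so the
  rad/s reading is the one consistent with the intended behaviour.
- **Subscripts.** K_xy / τ_xy = coupling *into* oscillator x *from*
  oscillator y (so the session-varying motor→attention coupling is `k_am`:
  2 passive, 10 tracking).
- **Integration.** Euler–Maruyama at dt = 25 ms: θ(t+dt) = θ(t) + dt·drift
  + √(2D·dt)·z, z ~ N(0,1), noise independent across oscillators. The
  stimulus phase is computed exactly (noiseless, uncoupled). Delays are
  rounded to integer steps (0.1 s → 4, 0.35 s → 14); internal A↔M delays
  are 0 (below one step). Delayed phases are read from the stored
  trajectory; before t = 0 each oscillator is extrapolated backwards at
  its natural frequency from a uniformly random initial phase.
- **Burn-in.** The first 100 s (1% of the reference 10⁴ s duration) are
  discarded from every downstream statistic so the coupled system reaches
  its stationary regime; a noiseless locked pair relaxes in ~1 s, so this
  is conservative.
- **PLV** is the *modulus* of the time-averaged unit phasor (the complex
  mean itself is not a scalar quality index) over the retained samples.
  A dt-halving check on a locked noiseless configuration moves PLV by
  < 1e−3, confirming the step is adequate for these statistics.
- **Presets.** Shared parameters: K_AS = 10, K_MA = 10, K_MS = 8 rad/s;
  τ_AS = 0.1 s; τ_AM = τ_MA = 0; D_A = 5, D_M = 10 rad²/s; ω_M = 1.7 Hz.
  Modality sets ω_A (1.5 / 0.7 Hz) and τ_MS (0.1 / 0.35 s); session sets
  K_AM (2 / 10). No parameter is fitted by optimisation anywhere —
  `preset()` accepts keyword overrides for exploration only.

`fit_to_behavior` scores a PLV curve against a performance curve as the R²
of the least-squares affine map (equivalently squared Pearson correlation),
computed on raw PLV; constant PLV raises a degenerate-fit signal rather
than returning 0 or 1.

## 6. Pipeline (`tempotrack.pipeline`)

One independent seed per stage (paradigm / observer / model) so any stage
can be re-run in isolation; seeds are echoed in every artifact and the
report. CSVs are written in a fixed dialect (UTF-8, '.' decimal, Hz and
seconds) so reruns of a fixed config are byte-identical — the tests check
digest equality. Configs are strict JSON (unknown keys rejected, errors
carry a JSON-pointer-style location); every headline number in the report
is recomputable from the emitted CSVs alone.

## 7. Problem sizes used in tests and analyses

Sweeps for the resonance analyses use 10 realizations × 1000 s per
frequency with 100 s burn-in: at these sizes the cubic-fit peak of the
mean PLV curve is stable to ≈ ±0.01 Hz across base seeds, which is an
order of magnitude tighter than the ±0.3 Hz band the checks use, while a
single sweep stays under ~15 s. The isolated-motor diagnostic uses the
full 10⁴ s (endpoint-slope SE = √(2D/T_total)/2π ≈ 0.007 Hz). The
sign-flip contrast uses 20 paired seeds (identical noise seed within each
passive/tracking pair, a variance-reduction choice) at 1000 s. Parameter
recovery uses 100 replicates of 40 trials × condition grid.

## 8. Known limitations

- The visual passive PLV peak estimate falls at ≈ 0.56–0.61 Hz, slightly
  below ω_A = 0.7 Hz: the condition grid has only two points below the
  peak and the PLV curve is skewed on the linear Hz axis, so the cubic's
  maximum shifts left. This is a property of the estimator-on-grid, shared
  with any analysis using it, not an integrator artifact.
- The auditory tracking−passive PLV gain at 1.7 Hz is small (≈ +0.015)
  relative to the visual disruption (≈ −0.13); detecting its sign reliably
  needs seed-paired contrasts and ≥ 20 replicates.
- Euler–Maruyama is first-order; dt = 25 ms is adequate for PLV-level
  statistics (see §5) but not for pathwise accuracy at strong coupling.
- The staircase threshold is a wandering estimate (§2); single tracks
  should not be over-interpreted.
- The observer emulates marginal statistics only (§3); no claim about
  mechanisms of human beat perception follows from recovery tests on it.
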