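"""Synthetic observer: statistical emulation of behavioural responses and taps.

This module generates datasets with the statistical structure the
behavioural estimators assume, so every downstream stage can be tested
without human data.  The observer is deliberately *not* a cognitive-process
model: accuracy is a Gaussian bump on the log2-frequency axis (an inverse-U
over tempo, peaking at a configurable optimum and attenuated by distractor
density), and taps are an isochronous schedule with Gaussian jitter, a
constant mean asynchrony, and a tempo-dependent rate compression.  Using a
generative family different from the cubic estimator keeps parameter
recovery a non-circular test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .paradigm import BeatSpec, TrialSequence, condition_set, generate_trial

__all__ = [
    "ObserverParams",
    "TapRecord",
    "SyntheticDataset",
    "accuracy_model",
    "simulate_responses",
    "simulate_taps",
    "generate_experiment",
]

#: Reference tempo of the rate-compression law: the spontaneous motor
#: rate (~1.7 Hz), at which produced and required tapping rates coincide.
RATE_COMPRESSION_REF_HZ = 1.7


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the statistical observer.

    optimal_tempo_hz
        Tempo of peak discrimination accuracy (Hz).
    tuning_width_oct
        SD of the accuracy bump on the log2-frequency axis (octaves).
    peak_accuracy
        Probability correct at the optimum with zero distractors.
    lapse_rate
        Probability of a stimulus-independent random guess.
    density_slope
        Linear accuracy attenuation per unit distractor density.
    tap_jitter_sd
        SD of tap timing jitter, as a fraction of the beat period.
    mean_asynchrony_s
        Constant tap-to-beat offset (seconds; negative = anticipatory).
    rate_compression
        Slope coupling produced tap rate to tempo: the mean inter-tap
        interval is T + rate_compression * (T - 1/1.7).  Negative values
        give faster-than-beat tapping at slow tempi and slower-than-beat
        at fast tempi.
    """

    optimal_tempo_hz: float = 1.4
    tuning_width_oct: float = 1.0
    peak_accuracy: float = 0.95
    lapse_rate: float = 0.02
    density_slope: float = 0.35
    tap_jitter_sd: float = 0.05
    mean_asynchrony_s: float = -0.03
    rate_compression: float = -0.2

    def __post_init__(self) -> None:
        if not self.optimal_tempo_hz > 0:
            raise ParameterError("optimal tempo must be positive")
        if not 0.5 <= self.peak_accuracy <= 1.0:
            raise ParameterError("peak accuracy must lie in [0.5, 1]")
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise ParameterError("lapse rate must lie in [0, 0.5]")
        if self.tap_jitter_sd < 0:
            raise ParameterError("tap jitter SD must be >= 0")
        if self.tuning_width_oct <= 0:
            raise ParameterError("tuning width must be positive")

    @classmethod
    def auditory_default(cls) -> "ObserverParams":
        """Auditory observer: optimum 1.4 Hz, anticipatory tapping (-30 ms)."""
        return cls()

    @classmethod
    def visual_default(cls) -> "ObserverParams":
        """Visual observer: optimum 0.7 Hz, broader/shallower tuning,
        reactive tapping (+50 ms), threshold density ~0.28 at 2 Hz."""
        return cls(
            optimal_tempo_hz=0.7,
            tuning_width_oct=1.5,
            density_slope=0.26,
            tap_jitter_sd=0.08,
            mean_asynchrony_s=0.05,
            rate_compression=-0.2,
        )


def accuracy_model(f_hz: float, density: float, params: ObserverParams) -> float:
    """Expected probability of a correct beat judgment at tempo ``f_hz``.

    p = 0.5 + (peak - 0.5) * exp(-(log2 f - log2 f*)^2 / (2 w^2))
            * max(0, 1 - density_slope * density),
    then mixed with the lapse rate: p <- (1 - lapse) p + lapse * 0.5.
    Symmetric in log-frequency about the optimum; chance level is 0.5
    (binary on/off-beat judgment).
    """
    if f_hz <= 0:
        raise ParameterError(f"tempo must be positive, got {f_hz}")
    x = math.log2(f_hz) - math.log2(params.optimal_tempo_hz)
    bump = math.exp(-(x * x) / (2.0 * params.tuning_width_oct**2))
    atten = max(0.0, 1.0 - params.density_slope * density)
    p = 0.5 + (params.peak_accuracy - 0.5) * bump * atten
    return (1.0 - params.lapse_rate) * p + params.lapse_rate * 0.5


@dataclass(frozen=True)
class TapRecord:
    """Tap onsets for one tracking trial, paired with its beat grid."""

    trial_id: int
    tap_times: np.ndarray
    beat_period: float
    beat_times: np.ndarray

    @property
    def n_taps(self) -> int:
        return len(self.tap_times)


def simulate_taps(
    seq: TrialSequence,
    params: ObserverParams,
    rng: np.random.Generator | int | None = None,
    trial_id: int = 0,
) -> TapRecord:
    """Simulate guided tapping for one trial.

    Tapping starts at the second reference (onset T) and continues to the
    end of the sequence.  The produced inter-tap interval follows the rate
    compression law ITI = T + c (T - 1/1.7); each tap additionally carries
    the constant mean asynchrony and independent Gaussian jitter of SD
    ``tap_jitter_sd * T``.
    """
    rng = np.random.default_rng(rng)
    T = seq.beat.period
    iti = T + params.rate_compression * (T - 1.0 / RATE_COMPRESSION_REF_HZ)
    if iti <= 0:
        raise ParameterError("rate compression yields a non-positive inter-tap interval")
    span = seq.events[-1].onset - T
    n_taps = int(math.floor(span / iti)) + 1
    k = np.arange(n_taps)
    jitter = rng.normal(0.0, params.tap_jitter_sd * T, size=n_taps) \
        if params.tap_jitter_sd > 0 else np.zeros(n_taps)
    taps = T + k * iti + params.mean_asynchrony_s + jitter
    return TapRecord(
        trial_id=trial_id,
        tap_times=taps,
        beat_period=T,
        beat_times=seq.beat_times(),
    )


def simulate_responses(
    sequences: Sequence[TrialSequence],
    params: ObserverParams,
    rng: np.random.Generator | int | None = None,
    session: str = "passive",
    start_trial_id: int = 0,
) -> pd.DataFrame:
    """Draw one Bernoulli correct/incorrect response per trial.

    The per-trial probability is :func:`accuracy_model` at the trial's
    tempo and density; trials are independent.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for i, seq in enumerate(sequences):
        p = accuracy_model(seq.beat.frequency_hz, seq.density, params)
        rows.append({
            "trial_id": start_trial_id + i,
            "condition_hz": seq.beat.frequency_hz,
            "density": seq.density,
            "deviant_on_beat": seq.deviant_on_beat,
            "response_correct": int(rng.random() < p),
            "session": session,
        })
    return pd.DataFrame(
        rows,
        columns=["trial_id", "condition_hz", "density", "deviant_on_beat",
                 "response_correct", "session"],
    )


@dataclass
class SyntheticDataset:
    """Trials and taps tables for one synthetic experiment, plus provenance."""

    trials: pd.DataFrame
    taps: pd.DataFrame
    params: ObserverParams
    seed: int | None

    def to_csv(self, trials_path, taps_path) -> None:
        self.trials.to_csv(trials_path, index=False)
        self.taps.to_csv(taps_path, index=False)


def generate_experiment(
    preset: str | Sequence[float],
    n_trials_per_condition: int,
    params: ObserverParams,
    *,
    density: float = 1.0,
    sessions: Sequence[str] = ("passive",),
    modality: Literal["auditory", "visual"] = "auditory",
    rng_seed: int | None = None,
    include_taps: bool = True,
) -> SyntheticDataset:
    """Generate a full synthetic experiment (responses, and taps when tracking).

    ``preset`` is a condition-set name (e.g. ``"auditory_8"``) or an
    explicit list of tempi in Hz.  Each session contributes
    ``n_conditions x n_trials_per_condition`` rows to the trials table
    (e.g. 8 conditions x 40 trials = 320 trials per session); tap rows are
    produced for tracking sessions only.  Deterministic for a fixed seed.
    """
    freqs = condition_set(preset) if isinstance(preset, str) else list(preset)
    rng = np.random.default_rng(rng_seed)
    trial_frames: list[pd.DataFrame] = []
    tap_rows: list[dict] = []
    tid = 0
    for session in sessions:
        for f in freqs:
            beat = BeatSpec(f, *(("fraction", 0.18) if modality == "visual" else ("fraction", 0.10)))
            seqs = [
                generate_trial(beat, density, deviant_on_beat=bool(rng.random() < 0.5),
                               modality=modality, rng=rng)
                for _ in range(n_trials_per_condition)
            ]
            frame = simulate_responses(seqs, params, rng, session=session,
                                       start_trial_id=tid)
            trial_frames.append(frame)
            if include_taps and session == "tracking":
                for j, seq in enumerate(seqs):
                    rec = simulate_taps(seq, params, rng, trial_id=tid + j)
                    for k, t in enumerate(rec.tap_times):
                        tap_rows.append({"trial_id": rec.trial_id, "tap_index": k,
                                         "tap_time_s": float(t)})
            tid += n_trials_per_condition
    trials = (
        pd.concat(trial_frames, ignore_index=True) if trial_frames
        else pd.DataFrame(columns=["trial_id", "condition_hz", "density",
                                   "deviant_on_beat", "response_correct", "session"])
    )
    taps = pd.DataFrame(tap_rows, columns=["trial_id", "tap_index", "tap_time_s"])
    return SyntheticDataset(trials=trials, taps=taps, params=params, seed=rng_seed)
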