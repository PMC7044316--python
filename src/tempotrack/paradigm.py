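"""Beat-discrimination trial sequences and adaptive difficulty calibration.

A trial is an isochronous stream of stimuli at a fixed beat frequency
(tempo).  Three *reference* stimuli establish the beat, followed by a
mixture of on-beat *targets* and off-beat *distractors*, and terminated by
a single *deviant* whose timing (on- vs off-beat) the observer must judge.
Task difficulty is controlled by the distractor density (distractors per
beat), calibrated per observer with a weighted up-down staircase targeting
75% correct at a 2 Hz tempo.

All times are continuous seconds; onsets are never snapped to a frame
grid (stimulus presentation is out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

from .errors import InfeasibleSequenceError, NonConvergenceError, ParameterError

__all__ = [
    "BeatSpec",
    "StimulusEvent",
    "TrialSequence",
    "StaircaseState",
    "Violation",
    "generate_trial",
    "validate_sequence",
    "condition_set",
    "run_staircase",
    "ISI_FLOOR_FRACTION",
    "MIN_TARGETS",
    "MAX_TARGETS",
    "MIN_TRIAL_DURATION",
]

#: Minimum inter-onset interval, as a fraction of the beat period.
ISI_FLOOR_FRACTION = 0.09
#: Hard bounds on the number of on-beat targets per trial
#: (references and deviant excluded).
MIN_TARGETS = 4
MAX_TARGETS = 22
#: Minimum trial span (first reference to deviant), seconds.
MIN_TRIAL_DURATION = 2.0

#: Printed condition sets (beat frequencies, Hz).
_CONDITION_PRESETS: dict[str, tuple[float, ...]] = {
    "auditory_8": (0.6, 0.7, 1.0, 1.3, 1.7, 2.2, 2.9, 3.8),
    "visual_10": (0.3, 0.4, 0.6, 0.7, 1.0, 1.3, 1.7, 2.2, 2.9, 3.8),
    "visual_8": (0.4, 0.7, 1.0, 1.3, 1.7, 2.2, 2.9, 3.8),
}

#: Nominal trial-duration bounds per modality, seconds.  Soft targets: the
#: 4-target floor overrides the upper bound at the slowest tempi.
DEFAULT_DURATION_BOUNDS = {"auditory": (2.0, 12.0), "visual": (2.0, 20.0)}


@dataclass(frozen=True)
class BeatSpec:
    """Tempo of an isochronous sequence and the stimulus-duration rule.

    ``duration_rule`` is either ``"fraction"`` (stimulus lasts
    ``duration_value`` of the inter-stimulus interval; 0.10 for tones,
    0.18 for gratings) or ``"fixed"`` (a constant length in seconds,
    22.5 ms in the tempo/duration-orthogonalised control).
    """

    frequency_hz: float
    duration_rule: Literal["fraction", "fixed"] = "fraction"
    duration_value: float = 0.10

    def __post_init__(self) -> None:
        if not (self.frequency_hz > 0 and math.isfinite(self.frequency_hz)):
            raise ParameterError(
                f"beat frequency must be a positive finite number, got {self.frequency_hz}"
            )
        if self.duration_rule == "fraction":
            if not 0 < self.duration_value < 1:
                raise ParameterError("fractional stimulus duration must lie in (0, 1)")
        elif self.duration_rule == "fixed":
            if self.duration_value <= 0:
                raise ParameterError("fixed stimulus duration must be positive")
        else:
            raise ParameterError(f"unknown duration rule {self.duration_rule!r}")

    @property
    def period(self) -> float:
        """Beat period in seconds (1 / frequency)."""
        return 1.0 / self.frequency_hz

    @property
    def stimulus_duration(self) -> float:
        """Duration of one stimulus in seconds under this spec's rule."""
        if self.duration_rule == "fraction":
            return self.duration_value * self.period
        return self.duration_value


@dataclass(frozen=True)
class StimulusEvent:
    onset: float
    role: Literal["reference", "target", "distractor", "deviant"]
    duration: float
    #: task-irrelevant feature of the deviant (spectral 785/660 Hz tone or
    #: blue/yellow grating); carried as metadata only.
    deviant_identity: str | None = None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ParameterError("event onset must be non-negative")
        if self.duration <= 0:
            raise ParameterError("event duration must be positive")


@dataclass(frozen=True)
class TrialSequence:
    """One beat-discrimination trial: an ordered stream of timestamped events."""

    beat: BeatSpec
    events: tuple[StimulusEvent, ...]
    density: float
    deviant_on_beat: bool
    deviant_offset: float
    modality: Literal["auditory", "visual"] = "auditory"

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])

    @property
    def n_targets(self) -> int:
        return sum(1 for e in self.events if e.role == "target")

    @property
    def n_distractors(self) -> int:
        return sum(1 for e in self.events if e.role == "distractor")

    @property
    def duration(self) -> float:
        """Trial span in seconds: first to last event onset."""
        return self.events[-1].onset - self.events[0].onset

    def beat_times(self) -> np.ndarray:
        """On-beat grid over the trial (references + targets + expected deviant beat)."""
        n_beats = int(round((self.events[-1].onset - self.deviant_offset) / self.beat.period))
        return np.arange(n_beats + 1) * self.beat.period


@dataclass
class Violation:
    """One failed sequence constraint: the rule name and offending event indices."""

    rule: str
    indices: tuple[int, ...]
    message: str


def condition_set(preset: str) -> list[float]:
    """Return the printed list of beat frequencies (Hz) for a named preset.

    Presets: ``auditory_8`` (0.6–3.8 Hz), ``visual_10`` (adds 0.3 and
    0.4 Hz), ``visual_8`` (the reduced tracking-session set).
    """
    try:
        return list(_CONDITION_PRESETS[preset])
    except KeyError:
        raise ParameterError(
            f"unknown condition preset {preset!r}; known: {sorted(_CONDITION_PRESETS)}"
        ) from None


def generate_trial(
    beat: BeatSpec,
    density: float,
    deviant_on_beat: bool,
    *,
    duration_bounds: tuple[float, float] | None = None,
    modality: Literal["auditory", "visual"] = "auditory",
    n_targets: int | None = None,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 1000,
) -> TrialSequence:
    """Generate one beat-discrimination trial sequence.

    Layout: references at 0, T, 2T; ``n_targets`` on-beat targets at
    3T … (2+n)T; the deviant one beat after the last target (plus a signed
    offset when off-beat, drawn uniformly from ±[0.09T, T/2]).  Distractors
    are placed sequentially and uniformly between the first target and the
    deviant; their count is Poisson with mean ``density × n_targets`` so the
    long-run count per beat equals ``density``.  Draws violating the
    inter-onset floor of 0.09T are rejected and redrawn (``max_attempts``
    draws in total per trial; exhausting them raises an
    :class:`InfeasibleSequenceError` naming the binding constraint).

    The target count is drawn uniformly over the feasible subset of
    [4, 22] given ``duration_bounds`` (defaults per modality), unless fixed
    explicitly via ``n_targets``.
    """
    if density < 0 or not math.isfinite(density):
        raise ParameterError(f"distractor density must be >= 0, got {density}")
    rng = np.random.default_rng(rng)
    T = beat.period
    floor = ISI_FLOOR_FRACTION * T
    if duration_bounds is None:
        duration_bounds = DEFAULT_DURATION_BOUNDS[modality]
    lo, hi = duration_bounds
    if not (0 < lo < hi):
        raise ParameterError(f"invalid duration bounds {duration_bounds}")

    # Feasible target counts: deviant expected at (3+n)T; even with the most
    # negative offset (-T/2) the span must clear the 2 s floor.
    n_min = max(MIN_TARGETS, math.ceil(max(MIN_TRIAL_DURATION, lo) / T - 2.5 - 1e-9))
    n_max = max(n_min, min(MAX_TARGETS, math.floor(hi / T) - 3))
    if n_min > MAX_TARGETS:
        raise InfeasibleSequenceError(
            f"cannot fit >= {MIN_TRIAL_DURATION} s into <= {MAX_TARGETS} targets at "
            f"{beat.frequency_hz} Hz",
            constraint="target-count",
        )
    if n_targets is None:
        n_targets = int(rng.integers(n_min, n_max + 1))
    elif not MIN_TARGETS <= n_targets <= MAX_TARGETS:
        raise ParameterError(f"n_targets must lie in [{MIN_TARGETS}, {MAX_TARGETS}]")

    dur = beat.stimulus_duration
    last_target = (2 + n_targets) * T
    if deviant_on_beat:
        offset = 0.0
    else:
        # uniform over ±[0.09T, T/2]; the lower bound keeps off-beat trials
        # discriminable in principle (mirrors the global inter-onset floor)
        mag = rng.uniform(floor, 0.5 * T)
        offset = mag if rng.random() < 0.5 else -mag
    deviant_onset = last_target + T + offset
    if deviant_onset - 0.0 < MIN_TRIAL_DURATION:  # defensive; n_min should prevent this
        raise InfeasibleSequenceError(
            "trial shorter than the 2 s floor", constraint="min-duration"
        )

    fixed_onsets = [i * T for i in range(3 + n_targets)] + [deviant_onset]
    n_distr = int(rng.poisson(density * n_targets))
    span_lo, span_hi = 3 * T, deviant_onset
    distr: list[float] = []
    if n_distr > 0:
        import bisect

        # sequential placement: each distractor is drawn uniformly on the
        # span and redrawn while it violates the inter-onset floor against
        # the events placed so far; the realised count stays Poisson(d*B)
        placed = sorted(fixed_onsets)
        budget = max_attempts
        for _ in range(n_distr):
            ok = False
            while budget > 0:
                budget -= 1
                cand = rng.uniform(span_lo, span_hi)
                i = bisect.bisect_left(placed, cand)
                left_ok = i == 0 or cand - placed[i - 1] >= floor
                right_ok = i == len(placed) or placed[i] - cand >= floor
                if left_ok and right_ok:
                    bisect.insort(placed, cand)
                    distr.append(cand)
                    ok = True
                    break
            if not ok:
                raise InfeasibleSequenceError(
                    f"could not place {n_distr} distractors with inter-onset floor "
                    f"{floor:.4f} s within {max_attempts} attempts (density {density}, "
                    f"{beat.frequency_hz} Hz)",
                    constraint="isi-floor",
                )

    events: list[StimulusEvent] = []
    for i in range(3):
        events.append(StimulusEvent(i * T, "reference", dur))
    for i in range(n_targets):
        events.append(StimulusEvent((3 + i) * T, "target", dur))
    for t in distr:
        events.append(StimulusEvent(float(t), "distractor", dur))
    events.sort(key=lambda e: e.onset)
    events.append(StimulusEvent(deviant_onset, "deviant", dur))

    seq = TrialSequence(
        beat=beat,
        events=tuple(events),
        density=density,
        deviant_on_beat=deviant_on_beat,
        deviant_offset=offset,
        modality=modality,
    )
    violations = validate_sequence(seq)
    if violations:  # should be unreachable; generation enforces every rule
        raise InfeasibleSequenceError(
            f"generated sequence violates constraints: {violations}",
            constraint=violations[0].rule,
        )
    return seq


def validate_sequence(seq: TrialSequence) -> list[Violation]:
    """Check every trial-sequence constraint; return one record per violation.

    An empty list means the sequence is valid.  Checked rules: strictly
    increasing onsets; three references at 0, T, 2T (within 1e-9 s); unique
    final deviant; 4–22 targets; every inter-onset interval >= 0.09T; trial
    span >= 2 s; deviant offset zero when on-beat, else 0.09T <= |offset| <= T/2.
    """
    out: list[Violation] = []
    T = seq.beat.period
    onsets = seq.onsets
    roles = [e.role for e in seq.events]

    bad = np.nonzero(np.diff(onsets) <= 0)[0]
    for i in bad:
        out.append(Violation("onsets-increasing", (int(i), int(i) + 1),
                             "onsets not strictly increasing"))

    if len(seq.events) < 4:
        out.append(Violation("event-count", (), "fewer than 4 events"))
        return out

    for i in range(3):
        if roles[i] != "reference" or abs(onsets[i] - i * T) > 1e-9:
            out.append(Violation("references", (i,),
                                 f"event {i} is not a reference at {i}*T"))

    dev_idx = [i for i, r in enumerate(roles) if r == "deviant"]
    if len(dev_idx) != 1 or dev_idx[0] != len(roles) - 1:
        out.append(Violation("deviant-last", tuple(dev_idx),
                             "sequence must end with its unique deviant"))

    n_targets = roles.count("target")
    if not MIN_TARGETS <= n_targets <= MAX_TARGETS:
        out.append(Violation("target-count", (),
                             f"{n_targets} targets outside [{MIN_TARGETS}, {MAX_TARGETS}]"))

    floor = ISI_FLOOR_FRACTION * T
    isi = np.diff(onsets)
    for i in np.nonzero(isi < floor)[0]:
        out.append(Violation("isi-floor", (int(i), int(i) + 1),
                             f"inter-onset interval {isi[i]:.6f} s < 0.09*T = {floor:.6f} s"))

    if onsets[-1] - onsets[0] < MIN_TRIAL_DURATION:
        out.append(Violation("min-duration", (),
                             f"trial span {onsets[-1] - onsets[0]:.3f} s < {MIN_TRIAL_DURATION} s"))

    if seq.deviant_on_beat:
        if seq.deviant_offset != 0.0:
            out.append(Violation("deviant-offset", (len(roles) - 1,),
                                 "on-beat deviant must have zero offset"))
    else:
        if not floor <= abs(seq.deviant_offset) <= 0.5 * T:
            out.append(Violation("deviant-offset", (len(roles) - 1,),
                                 f"off-beat offset {seq.deviant_offset:.6f} s outside "
                                 f"[0.09T, T/2]"))
    return out


@dataclass
class StaircaseState:
    """State of a weighted up-down staircase on distractor density.

    After a correct response the density moves up (harder) by ``step_up``;
    after an incorrect response it moves down (easier) by ``step_down``.
    With ``step_up : step_down = 1 : 3`` the procedure converges where
    P(correct) = step_down / (step_up + step_down) = 0.75.  Both steps
    shrink geometrically after each reversal.
    """

    current_density: float = 0.5
    step_up: float = 0.1
    step_down: float = 0.3
    target_accuracy: float = 0.75
    shrink: float = 0.95
    min_step: float = 0.03
    reversal_count: int = 0
    history: list[tuple[float, bool]] = field(default_factory=list)
    reversal_densities: list[float] = field(default_factory=list)
    _last_direction: int = 0  # +1 up, -1 down, 0 none yet

    def __post_init__(self) -> None:
        if self.current_density < 0:
            raise ParameterError("density must be >= 0")
        if self.step_up <= 0 or self.step_down <= 0:
            raise ParameterError("staircase steps must be positive")

    def update(self, response_correct: bool) -> None:
        """Record one response and move the density."""
        self.history.append((self.current_density, response_correct))
        direction = 1 if response_correct else -1
        if self._last_direction != 0 and direction != self._last_direction:
            self.reversal_count += 1
            self.reversal_densities.append(self.current_density)
            # shrink both steps, preserving the 1:3 ratio at the floor
            self.step_up = max(self.min_step, self.step_up * self.shrink)
            self.step_down = max(3.0 * self.min_step, self.step_down * self.shrink)
        self._last_direction = direction
        step = self.step_up if response_correct else -self.step_down
        self.current_density = max(0.0, self.current_density + step)


def run_staircase(
    responder: Callable[[TrialSequence], bool],
    *,
    beat: BeatSpec | None = None,
    state: StaircaseState | None = None,
    max_trials: int = 800,
    n_reversals: int = 6,
    rng: np.random.Generator | int | None = None,
    modality: Literal["auditory", "visual"] = "auditory",
) -> float:
    """Calibrate distractor density to ~75% correct with a weighted up-down staircase.

    On each trial a sequence is generated at the current density (on- vs
    off-beat deviant chosen at random) and judged by ``responder``.  The
    calibration tempo defaults to 2 Hz.  The full trial budget is run;
    the returned threshold is the mean density over the last
    ``n_reversals`` reversals.  Raises :class:`NonConvergenceError`
    (carrying the trajectory) if no reversal occurs within ``max_trials``.
    """
    if max_trials <= 0:
        raise ParameterError("max_trials must be positive")
    beat = beat or BeatSpec(2.0)
    state = state or StaircaseState()
    rng = np.random.default_rng(rng)
    for _ in range(max_trials):
        seq = generate_trial(
            beat, state.current_density, deviant_on_beat=bool(rng.random() < 0.5),
            modality=modality, rng=rng,
        )
        state.update(bool(responder(seq)))
    if state.reversal_count == 0:
        raise NonConvergenceError(
            f"no staircase reversal within {max_trials} trials", trajectory=state.history
        )
    tail = state.reversal_densities[-n_reversals:]
    return float(np.mean(tail))
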