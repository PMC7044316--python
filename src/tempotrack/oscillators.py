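"""Three delay-coupled noisy phase oscillators: stimulus (S), attention (A), motor (M).

The stimulus phase advances at a fixed rate (a purely periodic rhythm,
no noise); attention and motor are Kuramoto-style phase oscillators with
pairwise sine coupling, transmission delays, and additive white Gaussian
phase noise:

    dtheta_S/dt = 2*pi*omega_S
    dtheta_A/dt = 2*pi*omega_A + K_AM sin[theta_M(t - tau_AM) - theta_A]
                               + K_AS sin[theta_S(t - tau_AS) - theta_A] + xi_A(t)
    dtheta_M/dt = 2*pi*omega_M + K_MA sin[theta_A(t - tau_MA) - theta_M]
                               + K_MS sin[theta_S(t - tau_MS) - theta_M] + xi_M(t)

with <xi_i(t) xi_j(t')> = 2 D_i delta(t - t') delta_ij.  Subscripts on K
and tau are (target, source).  Natural frequencies are entered in Hz and
multiplied by 2*pi inside the integrator; K is in rad/s and D in rad^2/s.

Integration is Euler-Maruyama at dt = 25 ms: the noise increment is
sqrt(2 D dt) * z with z standard normal; delays are rounded to integer
steps; the pre-history is backward extrapolation at each oscillator's
natural frequency from uniformly random initial phases.  The first
``burn_in`` seconds are discarded from all downstream statistics so the
coupled dynamics reach equilibrium.

Entrainment quality is summarised by the phase-locking value
PLV = | (1/N) sum_t exp(i (theta_x(t) - theta_y(t))) |, the modulus of the
time-averaged unit phasor of the phase difference: 1 for perfect locking,
near 0 for no consistent phase relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateFitError, ParameterError

__all__ = [
    "ModelParams",
    "PhaseTrace",
    "PLVCurve",
    "preset",
    "simulate",
    "plv",
    "frequency_sweep",
    "mean_rotation_frequency",
    "fit_to_behavior",
]


@dataclass(frozen=True)
class ModelParams:
    """All model parameters.  K/tau subscripts read (target, source):
    e.g. ``k_am`` couples the motor phase *into* the attention equation."""

    omega_s: float = 1.0   # stimulus frequency, Hz (swept across conditions)
    omega_a: float = 1.5   # attention natural frequency, Hz
    omega_m: float = 1.7   # motor natural frequency, Hz (spontaneous tapping rate)
    k_as: float = 10.0     # stimulus -> attention coupling, rad/s
    k_am: float = 2.0      # motor -> attention coupling, rad/s (2 passive, 10 tracking)
    k_ma: float = 10.0     # attention -> motor coupling, rad/s
    k_ms: float = 8.0      # stimulus -> motor coupling, rad/s
    tau_as: float = 0.1    # stimulus -> attention delay, s
    tau_am: float = 0.0    # motor -> attention delay, s (internal, < dt)
    tau_ma: float = 0.0    # attention -> motor delay, s (internal, < dt)
    tau_ms: float = 0.1    # stimulus -> motor delay, s (0.1 auditory, 0.35 visual)
    d_a: float = 5.0       # attention noise intensity, rad^2/s
    d_m: float = 10.0      # motor noise intensity, rad^2/s
    dt: float = 0.025      # integration step, s
    duration: float = 1e4  # simulated time, s
    burn_in: float = 100.0  # discarded initial interval, s
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if not self.duration > self.burn_in >= 0:
            raise ParameterError("need duration > burn_in >= 0")
        for name in ("k_as", "k_am", "k_ma", "k_ms"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("tau_as", "tau_am", "tau_ma", "tau_ms"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.d_a < 0 or self.d_m < 0:
            raise ParameterError("noise intensities must be >= 0")
        for name in ("omega_s", "omega_a", "omega_m"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")

    def delay_steps(self, tau: float) -> int:
        """Delays are represented internally as round(tau / dt) steps."""
        return int(round(tau / self.dt))


def preset(
    modality: Literal["auditory", "visual"],
    session: Literal["passive", "tracking"],
    **overrides,
) -> ModelParams:
    """Printed parameter set for a modality x session condition.

    Modality fixes the attention natural frequency (1.5 Hz auditory,
    0.7 Hz visual) and the stimulus-to-motor delay (0.1 s vs 0.35 s);
    session fixes the motor-to-attention coupling (2 passive, 10 tracking).
    Everything else is shared.  Keyword overrides allow exploration.
    """
    if modality not in ("auditory", "visual"):
        raise ParameterError(f"unknown modality {modality!r}")
    if session not in ("passive", "tracking"):
        raise ParameterError(f"unknown session {session!r}")
    base = dict(
        omega_a=1.5 if modality == "auditory" else 0.7,
        tau_ms=0.1 if modality == "auditory" else 0.35,
        k_am=2.0 if session == "passive" else 10.0,
    )
    base.update(overrides)
    return ModelParams(**base)


@dataclass(frozen=True)
class PhaseTrace:
    """Unwrapped phases on the full time grid, plus the burn-in boundary."""

    t: np.ndarray
    theta_s: np.ndarray
    theta_a: np.ndarray
    theta_m: np.ndarray
    params: ModelParams
    burn_in_index: int

    @property
    def n_retained(self) -> int:
        """Number of post-burn-in samples entering downstream statistics."""
        return len(self.t) - self.burn_in_index

    def retained(self, which: str) -> np.ndarray:
        """Post-burn-in slice of ``'s'``, ``'a'`` or ``'m'`` phases."""
        arr = {"s": self.theta_s, "a": self.theta_a, "m": self.theta_m}[which]
        return arr[self.burn_in_index:]

    def plv_sa(self) -> float:
        """Stimulus-attention phase locking over the retained interval."""
        return plv(self.retained("s"), self.retained("a"))


def simulate(params: ModelParams, seed: int | None = None) -> PhaseTrace:
    """Integrate the three-oscillator model (Euler-Maruyama with delays).

    ``seed`` overrides ``params.seed``; the run is deterministic given the
    seed.  The stimulus phase is integrated exactly (it is noiseless and
    uncoupled); attention and motor are stepped at dt with delayed inputs
    read from the stored trajectory, extrapolated backwards at the natural
    frequency before t = 0.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n = int(round(params.duration / params.dt))
    dt = params.dt
    two_pi = 2.0 * math.pi
    ws, wa, wm = two_pi * params.omega_s, two_pi * params.omega_a, two_pi * params.omega_m
    das = params.delay_steps(params.tau_as)
    dam = params.delay_steps(params.tau_am)
    dma = params.delay_steps(params.tau_ma)
    dms = params.delay_steps(params.tau_ms)
    k_as, k_am, k_ma, k_ms = params.k_as, params.k_am, params.k_ma, params.k_ms

    s0, a0, m0 = rng.uniform(0.0, two_pi, size=3)
    za = (rng.standard_normal(n) * math.sqrt(2.0 * params.d_a * dt)).tolist() \
        if params.d_a > 0 else [0.0] * n
    zm = (rng.standard_normal(n) * math.sqrt(2.0 * params.d_m * dt)).tolist() \
        if params.d_m > 0 else [0.0] * n

    th_a = [a0]
    th_m = [m0]
    a, m = a0, m0
    sin = math.sin
    # plain-Python inner loop: scalar math here is several times faster than
    # per-step numpy calls, and the state is irreducibly sequential
    for i in range(n):
        j = i - dam
        m_delayed = th_m[j] if j >= 0 else m0 + wm * dt * j
        j = i - dma
        a_delayed = th_a[j] if j >= 0 else a0 + wa * dt * j
        s_for_a = s0 + ws * dt * (i - das)
        s_for_m = s0 + ws * dt * (i - dms)
        a_next = a + dt * (wa + k_am * sin(m_delayed - a) + k_as * sin(s_for_a - a)) + za[i]
        m_next = m + dt * (wm + k_ma * sin(a_delayed - m) + k_ms * sin(s_for_m - m)) + zm[i]
        a, m = a_next, m_next
        th_a.append(a)
        th_m.append(m)

    t = np.arange(n + 1) * dt
    burn_idx = int(math.ceil(params.burn_in / dt))
    return PhaseTrace(
        t=t,
        theta_s=s0 + ws * t,
        theta_a=np.array(th_a),
        theta_m=np.array(th_m),
        params=replace(params, seed=seed),
        burn_in_index=burn_idx,
    )


def plv(theta_x, theta_y) -> float:
    """Phase-locking value: |mean exp(i (theta_x - theta_y))|, in [0, 1].

    Invariant to a common constant phase offset and symmetric in its
    arguments.
    """
    x = np.asarray(theta_x, dtype=float)
    y = np.asarray(theta_y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("phase series must have equal length")
    if x.size == 0:
        raise ParameterError("phase series must be non-empty")
    return float(np.abs(np.mean(np.exp(1j * (x - y)))))


def mean_rotation_frequency(theta, dt: float) -> float:
    """Mean rotation rate in Hz from the unwrapped-phase endpoint slope:
    (theta_end - theta_start) / (2*pi * span)."""
    th = np.asarray(theta, dtype=float)
    if th.size < 2:
        raise ParameterError("need at least 2 samples")
    span = (th.size - 1) * dt
    return float((th[-1] - th[0]) / (2.0 * math.pi * span))


@dataclass(frozen=True)
class PLVCurve:
    """Mean and SD of stimulus-attention PLV across noise realizations,
    per stimulus frequency."""

    stim_freqs_hz: np.ndarray
    plv_mean: np.ndarray
    plv_sd: np.ndarray
    n_realizations: int
    label: str = ""
    #: per-(frequency, realization) PLV matrix and the seeds used
    plv_samples: np.ndarray | None = None
    seeds: np.ndarray | None = None


def frequency_sweep(
    params: ModelParams,
    stim_freqs_hz: Sequence[float],
    n_realizations: int,
    base_seed: int,
    label: str = "",
) -> PLVCurve:
    """Sweep the stimulus frequency across conditions; average PLV(S, A).

    For each frequency, ``n_realizations`` independent simulations are run
    with per-run seeds derived deterministically from ``base_seed``; the
    burn-in interval is discarded before the PLV.
    """
    freqs = list(stim_freqs_hz)
    if not freqs:
        raise ParameterError("empty stimulus-frequency list")
    if n_realizations < 1:
        raise ParameterError("need at least one realization")
    ss = np.random.SeedSequence(base_seed)
    child_seeds = ss.generate_state(len(freqs) * n_realizations) % (2**31)
    samples = np.empty((len(freqs), n_realizations))
    for i, f in enumerate(freqs):
        p = replace(params, omega_s=float(f))
        for r in range(n_realizations):
            s = int(child_seeds[i * n_realizations + r])
            samples[i, r] = simulate(p, seed=s).plv_sa()
    return PLVCurve(
        stim_freqs_hz=np.array(freqs, dtype=float),
        plv_mean=samples.mean(axis=1),
        plv_sd=samples.std(axis=1, ddof=1) if n_realizations > 1 else np.zeros(len(freqs)),
        n_realizations=n_realizations,
        label=label,
        plv_samples=samples,
        seeds=child_seeds.reshape(len(freqs), n_realizations),
    )


@dataclass(frozen=True)
class BehaviorFit:
    """Affine map from model PLV to behavioural proportion correct."""

    r_squared: float
    slope: float
    intercept: float


def fit_to_behavior(plv_curve: PLVCurve, perf_curve) -> BehaviorFit:
    """Score the model against behaviour: R^2 of the least-squares affine
    map from PLV to proportion correct across matched conditions
    (equivalently the squared Pearson correlation).
    """
    f_model = np.asarray(plv_curve.stim_freqs_hz, dtype=float)
    f_beh = np.asarray(perf_curve.conditions_hz, dtype=float)
    if f_model.shape != f_beh.shape or not np.allclose(f_model, f_beh, atol=1e-9):
        raise ParameterError("condition grids of model and behaviour do not match")
    x = np.asarray(plv_curve.plv_mean, dtype=float)
    y = np.asarray(perf_curve.prop_correct, dtype=float)
    if np.std(x) == 0:
        raise DegenerateFitError("PLV has zero variance across conditions")
    slope, intercept = np.polyfit(x, y, 1)
    if np.std(y) == 0:
        return BehaviorFit(r_squared=0.0, slope=float(slope), intercept=float(intercept))
    r = float(np.corrcoef(x, y)[0, 1])
    return BehaviorFit(r_squared=r * r, slope=float(slope), intercept=float(intercept))
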