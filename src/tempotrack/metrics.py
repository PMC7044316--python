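"""Behavioural estimators: performance curves, cubic optimal-tempo extraction,
tapping precision/CV, sensorimotor simultaneity, median splits, and the
AIC-based Bayes factor.

The optimal tempo is the local-maximum abscissa of a third-order polynomial
f(x) = a x^3 + b x^2 + c x + d fitted by least squares to per-condition
performance over tempo: with delta = b^2 - 3ac > 0,

    alpha = (-b - sqrt(delta)) / (3a)    (local maximum)
    beta  = (-b + sqrt(delta)) / (3a)    (local minimum)

A cubic is the most flexible model with a single unambiguous maximum.
Sensorimotor simultaneity Phi maps each tap's distance to its nearest beat
into a 2*pi space normalised to the beat period; zero is perfect
simultaneity and negative values are anticipatory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSplitError, ParameterError

__all__ = [
    "PerformanceCurve",
    "CubicFit",
    "TapMetrics",
    "BayesFactor",
    "performance_curve",
    "fit_cubic_optimal_tempo",
    "tapping_precision",
    "tapping_cv",
    "sensorimotor_simultaneity",
    "median_split",
    "bayes_factor_aic",
    "EVIDENCE_FOR_NULL_THRESHOLD",
]

#: A Bayes factor below 1/3 is taken as significant evidence for the null.
EVIDENCE_FOR_NULL_THRESHOLD = 1.0 / 3.0


@dataclass(frozen=True)
class PerformanceCurve:
    """Per-condition proportion correct with trial counts."""

    conditions_hz: np.ndarray
    prop_correct: np.ndarray
    n_trials: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.conditions_hz, dtype=float)
        if np.any(np.diff(c) <= 0):
            raise ParameterError("conditions must be strictly increasing")
        p = np.asarray(self.prop_correct, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ParameterError("proportions must lie in [0, 1]")
        if np.any(np.asarray(self.n_trials) < 1):
            raise ParameterError("every condition needs at least one trial")


def performance_curve(
    trials: pd.DataFrame,
    conditions: "np.ndarray | list[float] | None" = None,
    value_col: str = "response_correct",
    cond_col: str = "condition_hz",
) -> PerformanceCurve:
    """Aggregate a trials table into proportion correct per condition.

    If ``conditions`` is given, every listed condition must be present in
    the table (a condition with zero trials is an error).
    """
    if trials.empty:
        raise ParameterError("empty trials table")
    grouped = trials.groupby(cond_col)[value_col].agg(["mean", "count"]).sort_index()
    if conditions is not None:
        missing = [c for c in conditions if c not in set(grouped.index)]
        if missing:
            raise ParameterError(f"conditions with zero trials: {missing}")
        grouped = grouped.loc[list(conditions)]
    return PerformanceCurve(
        conditions_hz=grouped.index.to_numpy(dtype=float),
        prop_correct=grouped["mean"].to_numpy(dtype=float),
        n_trials=grouped["count"].to_numpy(),
    )


@dataclass(frozen=True)
class CubicFit:
    """Least-squares cubic over tempo and its local extrema.

    ``alpha`` (local max) and ``beta`` (local min) are defined iff the
    discriminant delta = b^2 - 3ac is positive and a != 0; otherwise both
    are None and ``no_optimum`` explains why (the curve has no interior
    maximum — distinct from a numerical failure, which raises).
    ``alpha_in_range`` flags whether alpha falls inside the data range.
    """

    a: float
    b: float
    c: float
    d: float
    delta: float
    alpha: float | None
    beta: float | None
    r_squared: float
    alpha_in_range: bool
    no_optimum: str | None = None

    def __call__(self, x):
        return ((self.a * x + self.b) * x + self.c) * x + self.d


def fit_cubic_optimal_tempo(
    freqs_hz,
    values,
    *,
    log_axis: bool = False,
    a_tol: float = 1e-12,
) -> CubicFit:
    """Fit f(x) = ax^3 + bx^2 + cx + d and extract the local maximum alpha.

    The fit is on the linear Hz axis by default (``log_axis=True`` fits on
    log2-frequency and maps alpha back to Hz).  Requires at least 4 distinct
    frequencies.  R^2 = 1 - SS_res / SS_tot.
    """
    x = np.asarray(freqs_hz, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("freqs and values must be 1-D of equal length")
    if len(np.unique(x)) < 4:
        raise ParameterError("cubic fit needs at least 4 distinct frequencies")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("non-finite input to cubic fit")
    xf = np.log2(x) if log_axis else x
    a, b, c, d = np.polyfit(xf, y, 3)
    fitted = np.polyval([a, b, c, d], xf)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    delta = b * b - 3.0 * a * c

    alpha = beta = None
    no_optimum = None
    if abs(a) <= a_tol:
        no_optimum = "leading coefficient is (numerically) zero: no cubic curvature"
    elif delta <= 0:
        no_optimum = "discriminant b^2 - 3ac <= 0: the cubic is monotone"
    else:
        sq = math.sqrt(delta)
        alpha = (-b - sq) / (3.0 * a)  # f''(alpha) = -2 sqrt(delta) < 0
        beta = (-b + sq) / (3.0 * a)
        if log_axis:
            alpha, beta = 2.0 ** alpha, 2.0 ** beta
    in_range = alpha is not None and float(np.min(x)) <= alpha <= float(np.max(x))
    return CubicFit(a=float(a), b=float(b), c=float(c), d=float(d),
                    delta=float(delta), alpha=alpha, beta=beta, r_squared=r2,
                    alpha_in_range=bool(in_range), no_optimum=no_optimum)


def tapping_precision(tap_times, beat_period: float) -> float:
    """Guided-tapping precision: mean tap frequency over tempo, in percent.

    100 * (1 / mean inter-tap interval) / (1 / T).  Requires >= 2 taps.
    """
    taps = np.asarray(tap_times, dtype=float)
    if len(taps) < 2:
        raise ParameterError("precision needs at least 2 taps (1 interval)")
    mean_iti = float(np.mean(np.diff(taps)))
    return 100.0 * beat_period / mean_iti


def tapping_cv(tap_times, beat_period: float) -> float:
    """Coefficient of variation of tapping: SD of inter-tap intervals / T.

    Sample SD (n-1 denominator).  Requires >= 3 taps (2 intervals).
    """
    taps = np.asarray(tap_times, dtype=float)
    if len(taps) < 3:
        raise ParameterError("CV needs at least 3 taps (2 intervals)")
    return float(np.std(np.diff(taps), ddof=1)) / beat_period


@dataclass(frozen=True)
class TapMetrics:
    """Per-trial tapping summary: precision, CV, and simultaneity indexes."""

    precision_pct: float | None
    cv: float | None
    phi_signed: float
    phi_abs: float
    phi_per_tap: np.ndarray


def sensorimotor_simultaneity(tap_times, beat_times, beat_period: float) -> TapMetrics:
    """Tap-to-beat temporal distance in a 2*pi space (sensorimotor simultaneity).

    Each tap is assigned to its nearest beat; the signed index is
    Phi = 2*pi*(tap - beat)/T wrapped to (-pi, pi], and the absolute index
    is |Phi|.  Trial values are arithmetic means over taps (values live
    near zero by construction).  Multiple taps may map to one beat.
    """
    taps = np.asarray(tap_times, dtype=float)
    beats = np.asarray(beat_times, dtype=float)
    if len(taps) == 0 or len(beats) == 0:
        raise ParameterError("simultaneity needs at least one tap and one beat")
    idx = np.searchsorted(beats, taps)
    idx = np.clip(idx, 1, len(beats) - 1) if len(beats) > 1 else np.zeros(len(taps), int)
    if len(beats) > 1:
        left = beats[idx - 1]
        right = beats[idx]
        nearest = np.where(taps - left <= right - taps, left, right)
    else:
        nearest = np.full(len(taps), beats[0])
    phi = 2.0 * np.pi * (taps - nearest) / beat_period
    # wrap to (-pi, pi]
    phi = -((-phi + np.pi) % (2.0 * np.pi) - np.pi)
    precision = tapping_precision(taps, beat_period) if len(taps) >= 2 else None
    cv = tapping_cv(taps, beat_period) if len(taps) >= 3 else None
    return TapMetrics(
        precision_pct=precision,
        cv=cv,
        phi_signed=float(np.mean(phi)),
        phi_abs=float(np.mean(np.abs(phi))),
        phi_per_tap=phi,
    )


def median_split(trials: pd.DataFrame, key: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a trials table at the sample median of ``key``.

    The table is stably sorted by the key; the low group receives the
    first ceil(n/2) rows (so with an odd count the median trial joins the
    low group, and ties at the median follow their side of the stable
    sort).  All-identical keys raise :class:`DegenerateSplitError`.
    """
    vals = trials[key].to_numpy(dtype=float)
    if len(vals) < 2 or not np.all(np.isfinite(vals)):
        raise ParameterError("median split needs >= 2 trials with finite keys")
    if np.all(vals == vals[0]):
        raise DegenerateSplitError(f"all values of {key!r} are identical")
    order = trials.sort_values(key, kind="stable")
    n_low = (len(order) + 1) // 2
    return order.iloc[:n_low], order.iloc[n_low:]


@dataclass(frozen=True)
class BayesFactor:
    """AIC-based Bayes factor of an effect hypothesis against the null."""

    value: float
    evidence_for_null: bool


def bayes_factor_aic(aic_null: float, aic_effect: float) -> BayesFactor:
    """BF(effect vs null) = exp((AIC_null - AIC_effect) / 2).

    A value below 1/3 is labelled significant evidence for the null.
    """
    if not (math.isfinite(aic_null) and math.isfinite(aic_effect)):
        raise ParameterError("AIC values must be finite")
    bf = math.exp((aic_null - aic_effect) / 2.0)
    return BayesFactor(value=bf, evidence_for_null=bf < EVIDENCE_FOR_NULL_THRESHOLD)
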