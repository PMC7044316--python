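"""Exception types shared across the package."""

from __future__ import annotations


class TempotrackError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TempotrackError, ValueError):
    """An input parameter is outside its valid domain."""


class InfeasibleSequenceError(TempotrackError, RuntimeError):
    """A trial sequence satisfying all constraints could not be constructed.

    ``constraint`` names the binding constraint (e.g. the inter-onset floor).
    """

    def __init__(self, message: str, constraint: str):
        super().__init__(message)
        self.constraint = constraint


class NonConvergenceError(TempotrackError, RuntimeError):
    """An adaptive staircase produced no reversal within the trial budget.

    Carries the full ``trajectory`` of (density, response) pairs so the run
    can be inspected.
    """

    def __init__(self, message: str, trajectory):
        super().__init__(message)
        self.trajectory = trajectory


class DegenerateSplitError(TempotrackError, ValueError):
    """A median split was requested on all-identical key values."""


class DegenerateFitError(TempotrackError, ValueError):
    """A regression target or predictor has zero variance."""


class ConfigError(TempotrackError, ValueError):
    """A run configuration failed schema validation."""
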