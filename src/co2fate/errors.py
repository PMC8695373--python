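"""Exception hierarchy for co2fate.

All domain errors derive from :class:`CO2FateError` so callers can catch the
package's failures with a single ``except`` clause while still letting
programming errors (TypeError etc.) propagate.
"""


class CO2FateError(Exception):
    """Base class for all co2fate domain errors."""


class SchemaError(CO2FateError):
    """A required column is missing from an input table."""


class RowError(CO2FateError):
    """A row of an input table could not be parsed.

    Carries the zero-based data-row index in :attr:`row_index`.
    """

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class ValidationError(CO2FateError, ValueError):
    """A domain-type invariant was violated."""


class AirDominatedError(CO2FateError, ValueError):
    """Sample helium is indistinguishable from (or dominated by) air helium."""


class EnvelopeError(CO2FateError, ValueError):
    """An observed delta lies outside the hybrid-model envelope.

    :attr:`distance` is the signed per-mil distance from the nearest envelope
    bound: positive above the pure-methanogenesis curve, negative below the
    pure-dissolution curve.
    """

    def __init__(self, distance: float, message: str | None = None):
        self.distance = distance
        side = "above pure-methanogenesis bound" if distance > 0 else "below pure-dissolution bound"
        super().__init__(message or f"outside model envelope: {distance:+.4f} permil {side}")


class CalibrationRangeError(CO2FateError, ValueError):
    """Temperature or equilibrium value outside a calibration's valid range."""


class PoorlyConstrainedError(CO2FateError):
    """More than half of the Monte-Carlo draws fell outside the attainable range."""


class InconsistentInputError(CO2FateError, ValueError):
    """Inputs contradict each other (e.g. f = 1 but observed delta != initial)."""
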