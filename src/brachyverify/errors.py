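"""Exception hierarchy for the verification engine.

Every error raised by the library derives from :class:`BrachyVerifyError`
so callers (notably the CLI) can map library failures onto exit codes
without enumerating failure modes.
"""

from __future__ import annotations


class BrachyVerifyError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(BrachyVerifyError, ValueError):
    """An argument lies outside the mathematical domain of an operation
    (e.g. a non-positive radius, an angle outside [0°, 180°])."""


class ConfigurationError(BrachyVerifyError, ValueError):
    """A source-model or generator configuration document is missing a
    field or carries an invalid value. The message names the field."""


class GeometryError(BrachyVerifyError, ValueError):
    """A transform matrix or channel geometry cannot yield a valid dwell
    (e.g. a zero-norm orientation column)."""


class NearSourceError(BrachyVerifyError):
    """The evaluation point is inside or touching the source capsule, so
    the line-source formalism is not evaluable there.

    Carries enough context for the verification layer to convert the
    exception into a failed-with-diagnosis result.
    """

    def __init__(self, message: str, *, dwell_index: int | None = None,
                 distance_cm: float | None = None):
        super().__init__(message)
        self.dwell_index = dwell_index
        self.distance_cm = distance_cm


class NumericError(BrachyVerifyError, ArithmeticError):
    """A fitted function produced a non-finite intermediate value; the
    message names the (r, theta) evaluation point."""


class DateError(BrachyVerifyError, ValueError):
    """Treatment date precedes the calibration date."""


class PlanError(BrachyVerifyError, ValueError):
    """A plan is structurally unusable (e.g. no dwell positions)."""


class ComparisonError(BrachyVerifyError, ValueError):
    """A verification point cannot be compared (non-positive TPS dose)."""


class FormatError(BrachyVerifyError, ValueError):
    """A plan file (DICOM or text dialect) violates the expected schema.
    The message names the offending element (channel, line, field)."""
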