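"""Exception hierarchy for luquant.

All user-facing failures derive from :class:`LuquantError` so callers can
catch one base class; subclasses distinguish malformed files, invalid
values, degenerate fits and missing calibration entries.
"""


class LuquantError(Exception):
    """Base class for all luquant errors."""


class FormatError(LuquantError):
    """A file does not conform to the spectral-image or calibration dialect."""


class ValidationError(LuquantError):
    """An input value violates a documented precondition."""


class NoSignalError(ValidationError):
    """An operation requiring counts was given an all-zero image."""


class NoPixelsError(ValidationError):
    """A region of interest selects no detector pixels."""


class FitError(LuquantError):
    """A least-squares fit failed to converge or is degenerate."""


class DegenerateDesignError(FitError):
    """The measurement design cannot identify the requested parameters
    (e.g. all attenuation coefficients effectively equal)."""


class CalibrationKeyError(LuquantError, KeyError):
    """A calibration-library lookup found no entry for the exact key."""

    def __str__(self) -> str:  # KeyError quotes its repr; keep the message readable
        return Exception.__str__(self)
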