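"""Exception hierarchy for clockorder.

All library errors derive from :class:`ClockOrderError` so callers can catch
one base class at pipeline boundaries.
"""


class ClockOrderError(Exception):
    """Base class for all clockorder errors."""


class DomainError(ClockOrderError, ValueError):
    """An argument lies outside its mathematical domain."""


class InvalidGridError(DomainError):
    """Axial grid is not strictly increasing or is too short."""


class TooFewSamplesError(DomainError):
    """Fewer samples than the autocorrelation machinery supports (N < 3)."""


class DegenerateProfileError(DomainError):
    """A constant (zero-variance) profile cannot be min-max normalized."""


class ZeroVarianceError(DomainError):
    """A constant series has no defined normalised autocorrelation."""


class NoSignalError(ClockOrderError):
    """Every column of a sample set is constant; the ordering objective is undefined."""


class NoOverlapError(ClockOrderError, ValueError):
    """Profiles share no common axial interval, so regridding is impossible."""


class RoiError(ClockOrderError, ValueError):
    """Region-of-interest specification is degenerate or out of image bounds."""


class PairingError(ClockOrderError, KeyError):
    """Control and partner sample sets cannot be matched by sample id."""


class FormatError(ClockOrderError, ValueError):
    """A data file violates the expected tabular format."""


class ConfigError(ClockOrderError, ValueError):
    """A run configuration is invalid."""
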