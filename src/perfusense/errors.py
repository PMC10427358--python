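"""Exception hierarchy for the perfusense toolkit.

Every error raised by the library derives from :class:`PerfusenseError`
so callers (and the CLI) can catch domain failures without masking bugs.
"""


class PerfusenseError(Exception):
    """Base class for all perfusense domain errors."""


class GridMismatchError(PerfusenseError):
    """Two spectra do not share the same wavelength grid."""


class FrameRoleError(PerfusenseError):
    """Dark/light frame roles are wrong for the requested operation."""


class EmptyBandError(PerfusenseError):
    """The requested emission band contains no grid points."""


class InvalidCalibrationError(PerfusenseError):
    """A calibration curve is unusable (non-positive slope, etc.)."""


class DegenerateDesignError(PerfusenseError):
    """A regression design has no spread (all concentrations identical)."""


class InsufficientDataError(PerfusenseError):
    """Not enough samples/replicates/trajectories for the operation."""


class ValidationError(PerfusenseError):
    """A scenario or configuration violates a physical invariant."""


class FormatError(PerfusenseError):
    """A data file is malformed; the message names the offending line."""


class ProtocolViolationError(PerfusenseError):
    """A clinical protocol precondition is not met (e.g. missing 30-min sample)."""
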