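"""Exception hierarchy.

Every failure mode that signals an unusable measurement raises; no function
in this package returns a silent NaN for contract violations.
"""


class RawPhotError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(RawPhotError, ValueError):
    """Frame/ROI dimensions violate a geometric precondition."""


class MalformedFrameError(RawPhotError, ValueError):
    """Packed raw buffer is too short or otherwise inconsistent."""


class FormatError(RawPhotError, ValueError):
    """Input file or array is not in the expected format."""


class ContractError(RawPhotError, ValueError):
    """An operation precondition (sample counts, ranges) is violated."""


class CoverageError(RawPhotError, ValueError):
    """A requested time lies outside the span of a kinetic series."""


class InvalidReferenceError(RawPhotError, ValueError):
    """Reference intensity does not exceed the dark signal (I0 <= Id)."""


class OpaqueSampleError(RawPhotError, ValueError):
    """Sample intensity does not exceed the dark signal (Is <= Id)."""


class ConfigurationError(RawPhotError, ValueError):
    """A session is missing required configuration (dark/reference/ROI)."""
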