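"""Exception hierarchy for coil-QA analysis failures.

Every error raised by this package derives from :class:`CoilQaError`, so
callers can distinguish analysis problems (bad series, missing phantom,
corrupt noise image) from programming errors.
"""


class CoilQaError(Exception):
    """Base class for all coil-QA errors."""


class InvalidDesignError(CoilQaError, ValueError):
    """Acquisition design parameters are unphysical or inconsistent."""


class MissingPairError(CoilQaError):
    """A slice/element group does not contain exactly one Signal and one Noise image."""


class InconsistentSeriesError(CoilQaError):
    """Images in one directory disagree on pixel spacing or matrix size."""


class NoPhantomError(CoilQaError):
    """No plausible phantom could be segmented on a Signal image."""


class GeometryError(CoilQaError):
    """A detected geometry or ROI violates its invariants (too small, out of bounds)."""


class ZeroNoiseError(CoilQaError):
    """Noise standard deviation is zero or negative — the Noise image is corrupt."""


class UndefinedPiuError(CoilQaError):
    """Percent image uniformity is undefined (maximum signal is zero)."""


class AlignmentError(CoilQaError):
    """Slice locations of two series that must be analyzed together do not match."""


class CoverageError(CoilQaError):
    """Required slice locations are missing from a series."""


class CoilMismatchError(CoilQaError):
    """Attempt to compare measurements from incompatible coil sets."""
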