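"""Exception hierarchy for enlfc.

All contract violations raise a subclass of :class:`EnlfcError` so callers can
catch pipeline failures without masking programming errors.
"""


class EnlfcError(Exception):
    """Base class for all enlfc errors."""


class DegenerateVoxelError(EnlfcError):
    """A voxel time series has (near-)zero variance and cannot be normalized
    or carried through dependence estimation."""

    def __init__(self, voxel: int, message: str | None = None):
        self.voxel = int(voxel)
        super().__init__(message or f"degenerate (zero-variance) voxel at column {voxel}")


class SampleSizeError(EnlfcError):
    """Too few observations for the requested estimator (the unbiased distance
    covariance denominator n(n-3) requires n >= 4)."""


class ContractError(EnlfcError):
    """Input violates a documented precondition (e.g. non-normalized time
    series passed to an estimator that requires Z-scored columns)."""


class DomainError(EnlfcError):
    """Numeric argument outside its mathematical domain."""


class ParameterError(EnlfcError):
    """Invalid configuration parameter (e.g. PCA order >= matrix size)."""


class AlignmentError(EnlfcError):
    """Inputs that must share a dimension or grid do not."""


class FormatError(EnlfcError):
    """On-disk input violates format expectations (grid mismatch, non-binary
    mask, empty mask...)."""


class InsufficientSampleError(EnlfcError):
    """Not enough scans/pairs for the requested statistical test."""


class UndefinedTestError(EnlfcError):
    """The requested test is undefined for these inputs (e.g. McNemar with no
    discordant pairs)."""
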