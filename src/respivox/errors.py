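"""Exception hierarchy for respivox.

Every failure mode named in the module contracts maps onto one of these, so
callers can catch ``RespivoxError`` for anything raised by the library.
"""


class RespivoxError(Exception):
    """Base class for all respivox errors."""


class ConfigurationError(RespivoxError):
    """Invalid configuration value (phantom, pipeline, or stage parameters)."""


class DomainError(RespivoxError):
    """A query location lies outside the valid parameter domain."""


class InvalidTransformError(RespivoxError):
    """Rotation matrix is not orthonormal with determinant +1."""


class DegenerateConfigurationError(RespivoxError):
    """Point correspondences are too few or collinear for a rigid fit."""


class RegistrationError(RespivoxError):
    """ICP could not find any correspondences within the pairing distance."""


class InsufficientPointsError(RespivoxError):
    """Cloud has too few points for the requested neighborhood operation."""


class ClassificationError(RespivoxError):
    """Boundary classification produced an empty or undersized class."""


class GeometryError(RespivoxError):
    """Geometric precondition violated (e.g. boundary below the back plane)."""


class OpenShellError(RespivoxError):
    """Flood fill leaked from the exterior into the model interior."""

    def __init__(self, message: str, leak_voxel=None):
        super().__init__(message)
        self.leak_voxel = leak_voxel


class IncompatibilityError(RespivoxError):
    """Grids with mismatched resolutions cannot share a template box."""


class UndefinedCorrelationError(RespivoxError):
    """Pearson correlation requested for a constant series."""


class DimensionError(RespivoxError):
    """Requested embedding dimensions exceed what is available."""


class FlatSignalError(RespivoxError):
    """Surrogate signal has no usable respiratory extrema."""


class PhaseError(RespivoxError):
    """A frame has no inhale/exhale label where one is required."""


class InsufficientDataError(RespivoxError):
    """A respiratory phase has too few samples for the polynomial degree."""


class AlignmentError(RespivoxError):
    """Series that must be frame-aligned have different lengths."""


class FormatError(RespivoxError):
    """Malformed point-cloud file."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
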