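"""Exception types raised across the pipeline."""


class CentropolError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CentropolError, ValueError):
    """A generator or analysis parameter violates its invariant."""


class GeometryError(CentropolError, ValueError):
    """Requested stack extent cannot contain the posed geometry."""


class ValidationError(CentropolError, ValueError):
    """An annotation or file record failed schema validation."""


class DegenerateAxisError(CentropolError, ValueError):
    """Long-axis estimation failed: the moment tensor is isotropic."""


class DegenerateRingError(CentropolError, ValueError):
    """Circle fit failed: landmark points are collinear."""


class NoSignalError(CentropolError, ValueError):
    """An intensity-based reference cannot be computed from an empty channel."""


class MeasurementError(CentropolError, ValueError):
    """A morphometric quantity is undefined on the given input."""


class BoundaryPeakError(MeasurementError):
    """A profile peak sits on the segment boundary; no subpixel refinement."""


class NoPeakError(MeasurementError):
    """No profile peak exceeds the prominence threshold."""
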