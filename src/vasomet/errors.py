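"""Exception hierarchy for section validation and degenerate analysis inputs."""


class VasometError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(VasometError, ValueError):
    """Input fails a structural precondition (shape, dtype, finiteness, range)."""


class ShapeMismatchError(ValidationError):
    """Masks belonging to one section do not share grid dimensions."""


class CalibrationMismatchError(ValidationError):
    """Masks belonging to one section do not share the same um/pixel calibration."""


class EmptyROIError(ValidationError):
    """The evaluable-tumor ROI contains no pixels."""


class NoVesselError(VasometError):
    """An operation requiring at least one vessel component received none."""


class DegenerateReferenceError(VasometError):
    """The overlap-coefficient reference marker is empty or fills the whole ROI."""


class DegenerateDataError(VasometError):
    """A statistical test received data it is undefined on (e.g. all-zero differences)."""
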