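"""Domain-specific exception types.

All inherit :class:`ValueError` so callers that do not care about the
distinction can catch a single base.
"""


class TumortexError(ValueError):
    """Base class for all package errors."""


class FormatError(TumortexError):
    """An image file could not be read or is not NRRD/NIfTI."""


class GeometryError(TumortexError):
    """Image and mask disagree on dimensions or voxel spacing."""


class EmptyROIError(TumortexError):
    """The segmentation mask contains no foreground voxel."""


class ParameterError(TumortexError):
    """A configuration value is out of its valid range."""


class SeparationError(TumortexError):
    """Logistic likelihood is unbounded (perfectly separated outcome)."""


class DesignError(TumortexError):
    """Design matrix is rank deficient."""


class ClassificationError(TumortexError):
    """Unknown histologic subtype label."""
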