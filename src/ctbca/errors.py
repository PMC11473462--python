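"""Exception hierarchy shared across the package.

Every error raised by ctbca derives from :class:`CTBCAError` so callers can
catch pipeline failures with a single except clause while still being able to
distinguish alignment problems from statistical degeneracies.
"""


class CTBCAError(Exception):
    """Base class for all ctbca errors."""


class ShapeError(CTBCAError):
    """Image does not have the expected dimensionality."""


class AlignmentError(CTBCAError):
    """A mask and CT volume do not share the same voxel grid."""


class ParameterError(CTBCAError):
    """A configuration value violates its constraint (e.g. non-positive spacing)."""


class DegenerateInputError(CTBCAError):
    """Input is structurally valid but the requested quantity is undefined
    (empty mask, zero denominator, zero-variance sample, ...)."""


class SampleSizeError(CTBCAError):
    """Too few observations for the requested statistical test."""


class ConvergenceError(CTBCAError):
    """Iterative fit failed to converge (includes complete separation)."""


class ConfigurationError(CTBCAError):
    """A required input (mask, column, file) is missing from the run configuration."""


class ExtrapolationError(CTBCAError):
    """A survival probability was requested beyond the observed follow-up."""


class CapacityError(CTBCAError):
    """Planted phantom regions do not fit into the requested grid."""
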