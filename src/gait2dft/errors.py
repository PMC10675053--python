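"""Exception hierarchy for the gait2dft pipeline.

Every stage raises a subclass of :class:`Gait2dftError` so callers can
catch pipeline failures without masking programming errors.
"""


class Gait2dftError(Exception):
    """Base class for all gait2dft errors."""


class FormatError(Gait2dftError):
    """Input file does not match the declared dialect (missing columns...)."""


class DataError(Gait2dftError):
    """Data violates a structural precondition (non-monotone time, too few rows...)."""


class RangeError(Gait2dftError):
    """A sample exceeds the sensor's physical range (saturation limit)."""


class ParameterError(Gait2dftError):
    """A configuration parameter is invalid."""


class StateError(Gait2dftError):
    """Operation called on an object in the wrong state (e.g. non-uniform series)."""


class SizeError(Gait2dftError):
    """Signal extract too short/long for the requested operation."""


class SelectionError(Gait2dftError):
    """A slab selection falls outside the recording."""


class ShapeError(Gait2dftError):
    """Array dimensions do not match between pipeline stages."""


class DegenerateDataError(DataError):
    """Data carries no usable variance (all rows identical, zero scatter...)."""


class DegenerateClusterError(DegenerateDataError):
    """A DF-score cluster has zero scatter; the criterion ratio is undefined."""


class ConfigError(Gait2dftError):
    """Run configuration is inconsistent (e.g. both real and synthetic input)."""
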