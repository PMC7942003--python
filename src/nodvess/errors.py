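"""Exception hierarchy for the nodvess pipeline.

Every stage raises a subclass of :class:`NodvessError` so batch drivers can
catch pipeline failures without masking programming errors.
"""


class NodvessError(Exception):
    """Base class for all nodvess pipeline errors."""


class FormatError(NodvessError):
    """A file could not be read as a supported volume format."""


class DimensionalityError(NodvessError):
    """An image is not a 3D scalar volume."""


class AlignmentError(NodvessError):
    """Two images that must share a grid do not."""


class SeedRejectedError(NodvessError):
    """The seed voxel intensity lies outside the region-growing HU window."""


class DegenerateNoduleError(NodvessError):
    """Morphological opening removed the whole grown region."""


class EmptyMaskError(NodvessError):
    """An operation that requires a nonempty mask received an empty one."""


class InsufficientDataError(NodvessError):
    """Too few valid samples/scales/directions to compute a statistic."""


class SpecError(NodvessError):
    """A phantom or cohort specification is internally inconsistent."""
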