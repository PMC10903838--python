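"""Exception hierarchy.

Every error raised intentionally by this package derives from
:class:`ProneLungError`, so pipeline drivers can distinguish data problems
(caught, recorded per subject) from genuine bugs (propagated).
"""


class ProneLungError(Exception):
    """Base class for all package errors."""


class FormatError(ProneLungError):
    """A file does not have the expected on-disk structure."""


class OrientationError(ProneLungError):
    """A volume's voxel axes cannot be mapped onto the package convention.

    Raised for oblique acquisitions (direction cosines further than the
    tolerance from axis-aligned after permutation); such scans must be
    resliced upstream.
    """


class ValidationError(ProneLungError):
    """Input content violates a documented contract (labels, ranges, CSV)."""


class GridMismatchError(ProneLungError):
    """Two images that must share a grid do not."""


class SegmentationFailureError(ProneLungError):
    """The lung segmenter produced no usable lung voxels."""


class SpecError(ProneLungError):
    """A phantom specification is infeasible (e.g. a folding deformation)."""


class DegenerateInputError(ProneLungError):
    """A statistical routine received input with no usable variation."""


class ConfigError(ProneLungError):
    """A run configuration file is invalid."""
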