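"""Exception hierarchy shared across the package.

All failures that a caller can meaningfully handle derive from
:class:`ProstalignError`; validation problems (bad geometry, bad config,
bad file content) derive from :class:`ValidationError`.
"""


class ProstalignError(Exception):
    """Base class for all package errors."""


class ValidationError(ProstalignError, ValueError):
    """An input violates a documented precondition or invariant."""


class BoundsError(ValidationError):
    """A voxel index lies outside the grid, naming the offending axis."""


class EmptyMaskError(ValidationError):
    """A segmentation mask has no foreground voxels.

    Signals an upstream segmentation failure: centroid-based alignment is
    undefined without at least one prostate voxel.
    """


class DegenerateInputError(ValidationError):
    """An image is constant (or otherwise degenerate) where contrast is required."""


class LandmarkFailureError(ProstalignError):
    """Pelvic bone landmark detection failed.

    The registration pipeline treats this as a signal to fall back to
    volume-center initialization rather than a hard abort.
    """


class DegenerateSimilarityError(ProstalignError):
    """Similarity metric undefined (constant region of interest in either image)."""


class InsufficientDataError(ValidationError):
    """Too few rater registrations to compute a consensus statistic."""


class MissingRoundError(ValidationError):
    """A rater lacks a matching-mode registration in one of the two rounds."""


class ConvergenceWarningFlag(UserWarning):
    """Optimizer hit its iteration cap; best-so-far result returned."""
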