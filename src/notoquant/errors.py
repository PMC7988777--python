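"""Exception hierarchy for the notoquant pipeline.

Every stage raises a subclass of :class:`NotoquantError` so that cohort
drivers can flag a failed fish and keep going instead of aborting the run.
"""


class NotoquantError(Exception):
    """Base class for all notoquant-specific failures."""


class GeometryError(NotoquantError):
    """A synthetic tube geometry is invalid (the centerline leaves the image)."""


class SegmentationError(NotoquantError):
    """Thresholding produced no notochord pixels.

    Carries the threshold that was applied so the operator can lower it.
    """

    def __init__(self, message: str, threshold: float | None = None):
        super().__init__(message)
        self.threshold = threshold


class CenterlineFitError(NotoquantError):
    """The polynomial centerline fit is under-determined or rank deficient."""


class ProfileError(NotoquantError):
    """Intensity-profile extraction failed (e.g. every sample out of bounds)."""
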