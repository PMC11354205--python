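"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`QctScreenError` so callers can
distinguish pipeline failures from programming errors, and so the CLI can
map stage failures to exit codes.
"""


class QctScreenError(Exception):
    """Base class for all pipeline errors."""


class OverlappingSpecsError(QctScreenError):
    """Vertebra specifications whose axial extents collide."""


class EmptyMaskError(QctScreenError):
    """Segmentation found no bone-range voxels (distinct from an empty result)."""


class AmbiguousOrderingError(QctScreenError):
    """Vertebra components overlap axially too much to order superior->inferior."""


class ROIInfeasibleError(QctScreenError):
    """Erosion annihilated the vertebral cross-section; no ROI can be placed."""


class ROITooSmallError(QctScreenError):
    """The placed ROI has fewer voxels than the configured minimum."""


class MeasurementFailureError(QctScreenError):
    """Neither L1 nor L2 could be measured (the exclusion category in cohort terms)."""


class InsufficientSamplesError(QctScreenError):
    """A phantom insert intersects fewer slices than calibration requires."""


class CalibrationFailureError(QctScreenError):
    """All candidate regression fits failed."""


class ProtocolMismatchError(QctScreenError):
    """A conversion model was applied to a volume acquired under a different protocol."""


class DomainError(QctScreenError):
    """HU input outside the fitted model's valid domain with clamping disabled."""
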