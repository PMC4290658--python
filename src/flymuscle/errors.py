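"""Exception hierarchy for the flymuscle pipeline."""


class FlyMuscleError(Exception):
    """Base class for all flymuscle errors."""


class FormatError(FlyMuscleError):
    """Input file violates the expected on-disk format (e.g. mixed page sizes)."""


class MetadataError(FlyMuscleError):
    """Acquisition metadata is missing required fields or has invalid values."""


class ValidationError(FlyMuscleError):
    """A data record violates an invariant (e.g. non-monotone timestamps)."""


class GeometryError(FlyMuscleError):
    """A polygon is degenerate, self-intersecting, or out of bounds."""


class SegmentationFailure(FlyMuscleError):
    """The level-set contour vanished; the caller should fall back to a manual ROI."""


class DegenerateHistogramError(FlyMuscleError):
    """All pixels share one grey value; no threshold separates classes."""


class MeasurementError(FlyMuscleError):
    """A morphometric quantity cannot be computed (e.g. empty skeleton)."""


class IntegrityError(FlyMuscleError):
    """A database operation would violate uniqueness or referential integrity."""


class MigrationError(FlyMuscleError):
    """The on-disk store was written by an incompatible schema version."""


class PhantomSpecError(FlyMuscleError):
    """A synthetic-stack specification is inconsistent (e.g. overlapping fibers)."""
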