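"""Exception hierarchy.

Every error raised by the library derives from :class:`IelocError` so the CLI
can catch one type and exit with a stage-tagged message.
"""


class IelocError(Exception):
    """Base class for all ieloc errors."""


class FormatError(IelocError):
    """A file could not be parsed in the expected format."""


class HeaderError(IelocError):
    """A volume header is unusable (e.g. non-invertible affine)."""


class BoundsError(IelocError):
    """A world coordinate maps outside the volume."""


class DetectionError(IelocError):
    """CT thresholding cannot proceed (e.g. constant volume)."""


class NoDensityError(IelocError):
    """No above-threshold CT voxel near a seed point."""

    def __init__(self, seed, message=None):
        self.seed = tuple(float(c) for c in seed)
        super().__init__(message or f"no CT density near seed {self.seed}")


class SnapFailure(IelocError):
    """No admissible CT voxel near a predicted contact position."""

    def __init__(self, predicted, message=None):
        self.predicted = tuple(float(c) for c in predicted)
        super().__init__(
            message or f"no snap candidate near predicted {self.predicted}"
        )


class PlanError(IelocError):
    """An electrode plan violates its invariants."""


class TableImportError(IelocError):
    """A per-electrode value table could not be merged."""


class ExportError(IelocError):
    """A table export precondition failed."""


class TopologyError(IelocError):
    """A surface mesh is empty or not closed."""


class MappingError(IelocError):
    """Electrode-to-vertex mapping has no usable electrodes."""


class PlacementError(IelocError):
    """A synthetic object does not fit inside its field of view."""
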