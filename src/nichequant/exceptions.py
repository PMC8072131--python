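"""Exception hierarchy shared across the package."""


class NicheQuantError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(NicheQuantError, ValueError):
    """A phantom or vessel specification violates its invariants."""


class PlacementError(NicheQuantError):
    """A requested object placement cannot be satisfied inside the grid."""


class SimulationError(NicheQuantError):
    """Time-lapse simulation failed (e.g. overcrowded field of view)."""


class RaggedPagesError(NicheQuantError):
    """Pages of a multi-page TIFF stack disagree in shape."""


class MissingSpacingError(NicheQuantError):
    """No voxel spacing available for a stack (no sidecar, no override)."""


class SchemaError(NicheQuantError, ValueError):
    """Records passed to a table writer do not share one schema."""


class ConfigError(NicheQuantError, ValueError):
    """Pipeline configuration is malformed (unknown key, bad type/range)."""


class DegenerateHistogramError(NicheQuantError):
    """Automatic thresholding on a constant-intensity image."""


class EmptyMaskError(NicheQuantError):
    """An operation that requires foreground received an empty mask."""


class EmptyNicheError(EmptyMaskError):
    """The union of channel masks is empty; no niche volume exists."""


class ContainmentError(NicheQuantError):
    """A mask that must be contained in another extends outside it."""


class InconsistencyError(NicheQuantError):
    """Internal geometric inconsistency (e.g. skeleton voxel outside mask)."""


class RankDeficiencyError(NicheQuantError):
    """A factorial design has an empty cell, so the model is not estimable."""


class StageError(NicheQuantError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
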