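"""Exception hierarchy. Every error carries a short machine-readable code."""


class DynopharmError(Exception):
    """Base class; ``code`` is a stable identifier for programmatic handling."""

    code = "error"

    def __init__(self, message: str = ""):
        super().__init__(message or self.code)


class LigandNotFoundError(DynopharmError):
    code = "ligand-not-found"


class FrameMismatchError(DynopharmError):
    code = "frame-mismatch"


class TooFewFramesError(DynopharmError):
    code = "too-few-frames"


class BadModelFileError(DynopharmError):
    code = "bad-model-file"


class NoGeometryError(DynopharmError):
    code = "no-geometry"


class EmptyWindowError(DynopharmError):
    code = "empty-window"


class DegenerateFitError(DynopharmError):
    code = "degenerate-fit"


class NoRingError(DynopharmError):
    code = "no-ring"


class NoModelsError(DynopharmError):
    code = "no-models"


class InsufficientModelsError(DynopharmError):
    code = "insufficient-models"


class InfeasibleScheduleError(DynopharmError):
    code = "infeasible-schedule"


class DecoyGenerationError(DynopharmError):
    code = "decoy-generation-failed"


class DegenerateLabelsError(DynopharmError):
    code = "degenerate-labels"
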