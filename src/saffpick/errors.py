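"""Package-wide error hierarchy.

Every error carries a short machine-readable ``code`` so CLI callers and
tests can match on failure kind without parsing prose.
"""


class SaffpickError(Exception):
    """Base class; ``code`` is a short kebab-case identifier."""

    code = "saffpick-error"

    def __init__(self, message: str = ""):
        super().__init__(message or self.code)


class ClassMissingError(SaffpickError):
    code = "class-missing"


class EmptyMaskError(SaffpickError):
    code = "empty-mask"


class RoiDegenerateError(SaffpickError):
    code = "roi-degenerate"


class RoiTooSmallError(SaffpickError):
    code = "roi-too-small"


class NoBranchLineError(SaffpickError):
    code = "no-branch-line"


class OddChannelsError(SaffpickError):
    code = "odd-channels"


class BadGroupsError(SaffpickError):
    code = "bad-groups"


class InputShapeError(SaffpickError):
    code = "input-shape"


class FusionShapeError(SaffpickError):
    code = "fusion-shape"


class EmptyDatasetError(SaffpickError):
    code = "empty-dataset"


class EmptyConfusionError(SaffpickError):
    code = "empty-confusion"


class SpecOutOfBoundsError(SaffpickError):
    code = "spec-out-of-bounds"


class BadPaletteError(SaffpickError):
    code = "bad-palette"


class StageError(SaffpickError):
    """Wraps an error raised inside a named pipeline stage."""

    code = "stage-error"

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        code = getattr(cause, "code", type(cause).__name__)
        super().__init__(f"stage '{stage}': {code}: {cause}")
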