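"""Exception hierarchy shared across the pipeline.

Every error carries a short machine-readable ``code`` and the CLI exit code
it maps to (2 = validation problem, 3 = missing upstream artifact).
"""
from __future__ import annotations


class PipelineError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 2

    def __init__(self, message: str, code: str = "PIPELINE") -> None:
        super().__init__(message)
        self.code = code


class ValidationError(PipelineError):
    """A value or field violates an invariant (bad config, negative count...)."""

    def __init__(self, message: str, code: str = "VALIDATION") -> None:
        super().__init__(message, code)


class StructuralError(ValidationError):
    """A table is structurally broken: duplicate keys, unpaired wells."""

    def __init__(self, message: str, code: str = "STRUCTURE") -> None:
        super().__init__(message, code)


class UndefinedRatioError(PipelineError):
    """A chemotactic index is undefined (zero control count)."""

    def __init__(self, message: str) -> None:
        super().__init__(message, "UNDEFINED_RATIO")


class DegenerateCompositionError(PipelineError):
    """Predicted well fractions are undefined (all indices zero)."""

    def __init__(self, message: str) -> None:
        super().__init__(message, "DEGENERATE_COMPOSITION")


class SingularFitError(PipelineError):
    """A calibration regression has no spread on the predictor axis."""

    def __init__(self, message: str) -> None:
        super().__init__(message, "SINGULAR_FIT")


class MissingArtifactError(PipelineError):
    """An upstream output file required by a stage is absent."""

    exit_code = 3

    def __init__(self, message: str) -> None:
        super().__init__(message, "MISSING_ARTIFACT")
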