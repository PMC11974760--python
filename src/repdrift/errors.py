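"""Exception hierarchy for repdrift."""


class RepdriftError(Exception):
    """Base class for all repdrift errors."""


class ConfigurationError(RepdriftError):
    """A simulation or pipeline configuration is invalid; the message names the field."""


class ValidationError(RepdriftError):
    """An input table is structurally invalid (missing columns, empty file)."""


class PipelineStageError(RepdriftError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause!r}")
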