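"""Exception hierarchy shared across the pipeline.

Exit-code mapping in the CLI: :class:`PipelineUsageError` -> 2,
:class:`FormatError` and :class:`StructureError` -> 3.
"""


class HerborganError(Exception):
    """Base class for all package errors."""


class FormatError(HerborganError):
    """An input file violates its declared dialect or schema."""


class StructureError(HerborganError):
    """A graph-assembly constraint is violated (e.g. conflicting node roles)."""


class DomainError(HerborganError, ValueError):
    """A value is outside its mathematical domain (counts, probabilities)."""


class PipelineUsageError(HerborganError):
    """The operation was called in a state or with arguments it cannot serve."""


class PipelineStageError(HerborganError):
    """A pipeline stage aborted; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
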