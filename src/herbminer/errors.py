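"""Exception hierarchy shared across the pipeline stages."""


class HerbMinerError(Exception):
    """Base class for all package errors."""


class FormatError(HerbMinerError):
    """An input table is missing required columns or is malformed."""


class RecordError(HerbMinerError):
    """A single record is invalid (e.g. a prescription with no herbs)."""


class EmptyInputError(HerbMinerError):
    """An operation received an empty corpus/matrix where data is required."""


class VocabularyError(HerbMinerError):
    """A herb name is not part of the corpus vocabulary."""


class ConfigurationError(HerbMinerError):
    """A configuration object violates its invariants or is infeasible."""


class GraphStructureError(HerbMinerError):
    """The co-occurrence graph cannot support the requested operation."""


class DivergenceError(HerbMinerError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


class InsufficientDataError(HerbMinerError):
    """Too few samples/nodes for the requested statistical procedure."""


class PipelineStageError(HerbMinerError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
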