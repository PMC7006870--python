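"""Exception hierarchy for froinet."""


class FroinetError(Exception):
    """Base class for all froinet errors."""


class InvalidDesignError(FroinetError):
    """Raised for malformed task designs (empty epoch lists, bad TR, ...)."""


class InvalidSpecError(FroinetError):
    """Raised for malformed HRF or cohort specifications."""


class UndefinedCorrelationError(FroinetError):
    """Raised when a Pearson correlation is requested for a constant series."""


class InvalidThresholdError(FroinetError):
    """Raised when a correlation threshold lies outside (0, 1)."""


class AbsentEdgeError(FroinetError):
    """Raised when link statistics are requested for an edge no subject has."""


class UndefinedNormalizationError(FroinetError):
    """Raised when shell normalization is requested for an edgeless graph."""


class SubjectIOError(FroinetError):
    """Raised for inconsistent on-disk subject data (shape/id mismatches)."""


class PipelineStageError(FroinetError):
    """Wraps a failure inside one pipeline stage with stage/subject context."""

    def __init__(self, stage: str, subject_id: str | None, cause: Exception):
        self.stage = stage
        self.subject_id = subject_id
        who = f" (subject {subject_id})" if subject_id else ""
        super().__init__(f"stage '{stage}'{who} failed: {cause}")
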