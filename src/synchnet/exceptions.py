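"""Package exception hierarchy."""


class SynchnetError(Exception):
    """Base class for all synchnet errors."""


class InsufficientEpochsError(SynchnetError):
    """Fewer artifact-free epochs survived screening than were requested."""


class DegenerateCovarianceError(SynchnetError):
    """A sensor has (numerically) zero variance; noise whitening is undefined."""


class PipelineStageError(SynchnetError):
    """A pipeline stage failed; carries the stage and subject for context."""

    def __init__(self, stage: str, subject, original: BaseException):
        self.stage = stage
        self.subject = subject
        self.original = original
        super().__init__(
            f"pipeline stage '{stage}' failed for subject {subject!r}: {original}"
        )
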