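"""Package-wide exception types."""


class MutaccumError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(MutaccumError, ValueError):
    """A parameter is outside its mathematical or biological domain."""


class DegenerateFitError(MutaccumError, RuntimeError):
    """The data cannot constrain the model (e.g. all survivals identical)."""


class UnclassifiableEventError(MutaccumError, ValueError):
    """A mutation event does not fit any of the seven categories."""


class PipelineError(MutaccumError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
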