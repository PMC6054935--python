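"""Exception hierarchy."""


class PsanetError(Exception):
    """Base class for all package errors."""


class ParameterError(PsanetError, ValueError):
    """Invalid simulation or configuration parameters."""


class ConsistencyError(PsanetError, ValueError):
    """Inputs that are individually valid but mutually inconsistent."""


class DomainError(PsanetError, ValueError):
    """A value outside the mathematical domain of an operation."""


class StageError(PsanetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
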