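"""Exception types shared across the package."""


class LitmineError(Exception):
    """Base class for all package-specific errors."""


class CorpusFormatError(LitmineError, ValueError):
    """The corpus file is not parseable as the documented JSON dialect."""


class ValidationError(LitmineError, ValueError):
    """A domain object violates one of its invariants."""


class LexiconError(LitmineError, ValueError):
    """The entity lexicon is malformed."""


class StateError(LitmineError, RuntimeError):
    """An operation was called before its prerequisites were established."""


class ContractError(LitmineError, ValueError):
    """Inputs violate an operation's contract (e.g. mixed-type comention table)."""


class PipelineStageError(LitmineError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
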