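"""Exception hierarchy."""


class MicroscapeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MicroscapeError, ValueError):
    """Invalid configuration (gates, rules, mixtures, model parameters)."""


class EmptyInputError(MicroscapeError, ValueError):
    """An operation received an empty input it cannot handle."""


class InsufficientCellsError(MicroscapeError, ValueError):
    """Fewer cells than an operation's stated minimum."""


class StageError(MicroscapeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
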