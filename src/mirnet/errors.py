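"""Exception hierarchy shared by all pipeline stages."""


class MirnetError(Exception):
    """Base class for all package errors."""


class ConfigError(MirnetError):
    """A simulation or pipeline configuration value is invalid.

    The message names the offending field.
    """


class InputError(MirnetError):
    """An input table, matrix or file violates a stage's contract."""


class StageError(MirnetError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
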