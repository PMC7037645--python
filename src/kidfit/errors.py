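"""Exception hierarchy for the kidfit package."""


class KidFitError(Exception):
    """Base class for all kidfit errors."""


class ConfigurationError(KidFitError):
    """A configuration object is invalid or incomplete; the message names the field."""


class InputError(KidFitError):
    """A data input violates a precondition (bad value, wrong shape, out of range)."""


class StageError(KidFitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
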