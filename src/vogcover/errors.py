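"""Exception hierarchy shared across the pipeline.

``InputError`` maps to exit code 1 in the CLI (unreadable/invalid input),
``ComputationError`` to exit code 2 (a stage ran but could not produce a
result, e.g. a session with no usable alternation cycles).
"""


class VogError(Exception):
    """Base class for all package errors."""


class InputError(VogError):
    """Invalid or unreadable input (file, schedule, parameters)."""


class ComputationError(VogError):
    """A processing stage failed to produce a result."""


class UnmeasurableSessionError(ComputationError):
    """No usable alternation cycle survived quality gating."""


class StageError(ComputationError):
    """Pipeline stage failure carrying the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
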