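"""Exception hierarchy shared across the package."""


class DropqsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DropqsError, ValueError):
    """A precondition on user-supplied values was violated."""


class ValidationError(DropqsError):
    """A CSV file or configuration failed schema validation."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class PipelineError(DropqsError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
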