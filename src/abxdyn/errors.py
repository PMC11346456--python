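"""Exception hierarchy shared across the package."""


class AbxdynError(Exception):
    """Base class for all package-specific errors."""


class TimelineFormatError(AbxdynError, ValueError):
    """The CSV file does not have the expected header / shape."""


class TimelineValidationError(AbxdynError, ValueError):
    """A timeline record violates a table invariant (years, ordering, names)."""


class EstimationError(AbxdynError, RuntimeError):
    """A fit cannot be performed (no events, degenerate or flat likelihood)."""


class PipelineError(AbxdynError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
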