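"""Exception hierarchy shared across the package."""


class FibrodiffError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FibrodiffError, ValueError):
    """An invalid configuration value; the message names the violated constraint."""


class ParseError(FibrodiffError, ValueError):
    """A malformed input file; carries the offending line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AnalysisError(FibrodiffError, ValueError):
    """Inputs that are structurally valid but unusable for the requested analysis."""


class PipelineError(FibrodiffError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
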