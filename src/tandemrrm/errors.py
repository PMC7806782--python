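"""Exception hierarchy shared across the package."""


class TandemRRMError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TandemRRMError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line_number=None):
        self.path = path
        self.line_number = line_number
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line_number is not None:
            loc += f" at line {line_number}"
        super().__init__(message + loc)


class ValidationError(TandemRRMError):
    """An input violated a documented invariant."""


class FitError(TandemRRMError):
    """A model fit could not be performed at all (bad inputs, empty set)."""


class DegenerateGeometryError(TandemRRMError):
    """Coordinate input is too degenerate for the requested operation."""


class PipelineError(TandemRRMError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
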