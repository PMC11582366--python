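"""Exception hierarchy shared across the package."""


class IsoanchorError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IsoanchorError):
    """An input violated a documented precondition or invariant."""


class ParseError(IsoanchorError):
    """A tabular input could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NewickParseError(ParseError):
    """A Newick string could not be parsed into a rooted tree."""


class StageError(IsoanchorError):
    """A pipeline stage failed; names the stage for the run log."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
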