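"""Exception types shared across the pipeline."""


class TwinmethError(Exception):
    """Base class for all pipeline errors."""


class ParseError(TwinmethError, ValueError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SizingError(TwinmethError, ValueError):
    """A simulation layout that does not fit on the configured chromosomes."""


class InsufficientDataError(TwinmethError, ValueError):
    """Too few observations to compute the requested statistic."""


class UndefinedStatisticError(TwinmethError, ValueError):
    """A statistic whose value is undefined for this input (e.g. zero variance)."""


class KeySpaceMismatchError(TwinmethError, ValueError):
    """Comparison sets that do not share a promoter key universe."""


class FixtureIntegrityError(TwinmethError, ValueError):
    """A packaged fixture table whose checksum does not match the shipped digest."""
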