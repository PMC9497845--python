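"""Exception hierarchy shared across the package."""


class LsdlSpectraError(Exception):
    """Base class for all package errors."""


class FormatError(LsdlSpectraError):
    """Structurally malformed input file (ragged rows, bad JCAMP block, ...)."""


class ParseError(LsdlSpectraError):
    """A cell or token could not be converted to a number."""


class ValidationError(LsdlSpectraError):
    """Input violates a domain invariant (grids, monotonicity, counts, ...)."""


class DegenerateInputError(LsdlSpectraError):
    """Input is numerically degenerate for the requested computation
    (constant series, zero variance, zero power)."""


class SearchFailureError(LsdlSpectraError):
    """Threshold search found no feasible candidate."""


class ConfigError(LsdlSpectraError):
    """Invalid run configuration."""


class StageError(LsdlSpectraError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
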