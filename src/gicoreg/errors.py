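"""Exception hierarchy.

``ValidationError`` (and subclasses) signal bad user input or configuration
and map to CLI exit code 2; every other :class:`GicoregError` maps to exit
code 1.
"""


class GicoregError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(GicoregError):
    """Invalid input data or configuration."""


class ConfigError(ValidationError):
    """Invalid simulation or pipeline configuration."""


class ParseError(ValidationError):
    """Malformed input file; carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EmptyInputError(ValidationError):
    """An operation received an empty profile, matrix, or table."""


class MissingChromosomeError(ValidationError):
    """A requested chromosome has no segments in the profile."""


class DegenerateDesignError(ValidationError):
    """A model design is degenerate (single group, constant covariate)."""


class ConvergenceError(GicoregError):
    """An iterative fit failed to converge."""


class SearchFailureError(GicoregError):
    """A cutoff search found no admissible candidate."""


class EmptyResultError(GicoregError):
    """A join or filter retained nothing; carries per-filter counts."""

    def __init__(self, message: str, counts: dict | None = None):
        self.counts = dict(counts or {})
        if self.counts:
            message = f"{message} [{self.counts}]"
        super().__init__(message)
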