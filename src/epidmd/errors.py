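"""Exception hierarchy for the incidence-panel pipeline.

Validation problems (bad configuration, malformed input files) and runtime
problems (degenerate matrices, failed model fits) are kept in separate
branches so callers — in particular the command-line layer — can map them to
distinct exit codes.
"""


class EpidmdError(Exception):
    """Base class for all package errors."""


class ValidationError(EpidmdError):
    """Invalid configuration or input that violates a declared contract."""


class SchemaError(ValidationError):
    """A required column is absent from an input file."""


class RowParseError(ValidationError):
    """A row of an input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class PanelIntegrityError(ValidationError):
    """Conflicting duplicate records or other panel-level inconsistency."""


class EmptyPanelError(ValidationError):
    """An operation produced or received a panel with no counties."""


class InsufficientDataError(ValidationError):
    """Too few time points for the requested operation."""


class ComputationError(EpidmdError):
    """Numerical/runtime failure during model fitting or prediction."""


class RankError(ComputationError):
    """Requested truncation rank exceeds the numerical rank."""

    def __init__(self, requested: int, numerical_rank: int):
        super().__init__(
            f"requested rank {requested} exceeds numerical rank {numerical_rank}"
        )
        self.requested = requested
        self.numerical_rank = numerical_rank


class DegenerateInputError(ComputationError):
    """Input matrix is identically zero or otherwise unusable."""


class NoSteadyModeError(ComputationError):
    """No near-zero-frequency eigenvalue within the angular tolerance."""


class UndefinedMetricError(ComputationError):
    """A metric is undefined for the given inputs (e.g. zero rank variance)."""
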