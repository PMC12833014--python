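"""Exception types shared across the pipeline."""


class PvSignalError(Exception):
    """Base class for package errors."""


class ConfigurationError(PvSignalError):
    """Invalid simulation or analysis configuration."""


class EmptyDatabaseError(PvSignalError):
    """An operation received a database with no usable records."""


class MapFormatError(PvSignalError):
    """A user-supplied mapping file has a malformed row."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ConvergenceError(PvSignalError):
    """Optimization failed to converge; carries the best point found."""

    def __init__(self, message: str, best=None, diagnostics: dict | None = None):
        super().__init__(message)
        self.best = best
        self.diagnostics = diagnostics or {}


class RankDeficiencyError(PvSignalError):
    """Design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )
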