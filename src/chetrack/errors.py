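"""Exception hierarchy shared across the pipeline stages."""


class ChetrackError(Exception):
    """Base class for all package errors."""


class ConfigError(ChetrackError, ValueError):
    """A simulation or pipeline configuration field is invalid."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class DataError(ChetrackError, ValueError):
    """Input microdata violate a precondition (e.g. nonpositive consumption)."""


class FitError(ChetrackError, ValueError):
    """A model could not be fitted (insufficient points)."""


class DegenerateFitError(FitError):
    """The regressor has zero variance and the system is inconsistent."""


class EnsembleError(ChetrackError, RuntimeError):
    """No admissible model could be fitted for the ensemble."""


class DesignError(ChetrackError, ValueError):
    """An interrupted time-series design matrix is rank deficient."""


class ParseError(ChetrackError, ValueError):
    """A CSV table does not match its documented schema."""
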