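"""Exception types shared across the package."""


class StreetPAError(Exception):
    """Base class for package errors."""


class ConfigError(StreetPAError, ValueError):
    """Invalid configuration value or combination."""


class DimensionError(StreetPAError, ValueError):
    """A vector or matrix has an incompatible shape."""


class TrainingError(StreetPAError, ValueError):
    """The scoring model cannot be fitted from the given data."""


class CalibrationError(StreetPAError, RuntimeError):
    """The calibration stream cannot satisfy its preconditions."""


class AggregationError(StreetPAError, ValueError):
    """Spatial aggregation failed (e.g. an empty buffer)."""


class RankDeficiencyError(StreetPAError, ValueError):
    """Design matrix is rank deficient; carries the aliased column names."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(f"design matrix is rank deficient; aliased terms: {self.aliased}")


class ValidationError(StreetPAError, ValueError):
    """Input table failed validation; message names the offending rows."""
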