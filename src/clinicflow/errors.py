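"""Exception hierarchy for clinicflow."""


class ClinicFlowError(Exception):
    """Base class for all clinicflow errors."""


class ConservationError(ClinicFlowError):
    """Monthly ledger counts do not partition the total."""


class UndefinedRateError(ClinicFlowError):
    """Rates requested from a ledger with zero total appointments."""


class UndefinedEntropyError(ClinicFlowError):
    """Entropy of an empty class distribution is undefined."""


class SchemaError(ClinicFlowError):
    """Feature name or feature layout does not match the dataset schema."""


class FitError(ClinicFlowError):
    """Model fitting failed (e.g. empty training data)."""


class UpdateError(ClinicFlowError):
    """Incremental model update rejected (schema mismatch)."""


class ConfigurationError(ClinicFlowError):
    """Invalid configuration value (e.g. callback horizon below 60 min)."""


class PromotionError(ClinicFlowError):
    """Substitute promotion preconditions violated."""


class CorrelationError(ClinicFlowError):
    """Correlation undefined (length mismatch or constant series)."""


class DegreesOfFreedomError(ClinicFlowError):
    """Sample standard deviation requires at least two observations."""


class FormatError(ClinicFlowError):
    """Input file does not match the declared format."""
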