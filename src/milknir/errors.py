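"""Exception hierarchy shared across the package."""


class MilkNirError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MilkNirError):
    """A CSV file or table does not conform to the expected schema."""


class DomainError(MilkNirError):
    """Input values are outside the mathematical domain of an operation."""


class ConfigError(MilkNirError):
    """A configuration object is internally inconsistent or infeasible."""


class NotFittedError(MilkNirError):
    """A trainable step was applied before being fitted on calibration data."""


class ConvergenceError(MilkNirError):
    """An iterative algorithm failed to converge within its iteration budget."""


class RankError(MilkNirError):
    """Requested model complexity exceeds the effective rank of the data."""
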