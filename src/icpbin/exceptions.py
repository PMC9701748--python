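"""Exception hierarchy.

All package errors derive from :class:`ICPError` so callers (and the CLI)
can distinguish configuration mistakes from data problems.
"""


class ICPError(Exception):
    """Base class for all icpbin errors."""


class ConfigError(ICPError):
    """A configuration (column roles, rules, arguments) is invalid."""


class DataError(ICPError):
    """The supplied data violate a precondition."""


class StructuralError(ConfigError):
    """A structural causal model specification is malformed (e.g. cyclic)."""


class ContractViolationError(ConfigError):
    """An intervention targets the outcome or its generating mechanism."""


class DegenerateOutcomeError(DataError):
    """The binary outcome has a single observed class; logistic MLE undefined."""


class UntestableEnvironmentError(DataError):
    """An environment level has too few rows (<2) for the two-sample test,
    or an environment column does not show both levels."""


class InvalidEnvironmentError(DataError):
    """A candidate environment column cannot be dichotomized into two levels."""
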