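"""Exception hierarchy for medroute."""


class MedrouteError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MedrouteError, ValueError):
    """A scenario, run, or model configuration is invalid.

    The message names the offending field.
    """


class CohortValidationError(MedrouteError, ValueError):
    """A cohort table violates the documented data dictionary."""


class LifeTableCoverageError(MedrouteError, KeyError):
    """A life-table lookup fell outside the table's (age, sex, year) grid."""


class ConvergenceError(MedrouteError, RuntimeError):
    """A model fit failed to converge (e.g. separation in logistic regression)."""


class UndefinedProportionMediatedError(MedrouteError, ArithmeticError):
    """The proportion mediated is undefined because the total effect is null."""
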