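"""Exception and warning hierarchy.

Errors partition into configuration (bad user input before any data is
touched), data (the table violates its contract), and estimation (the
statistical procedure cannot produce a valid answer). Positivity failures
are a species of estimation error because they are estimand-specific.
"""


class BinateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BinateError):
    """Invalid run configuration: missing columns, bad specs, bad flags."""


class DataError(BinateError):
    """The input table violates its contract (missing cells, bad domain)."""


class EstimationError(BinateError):
    """The requested estimate cannot be computed on this data."""


class PositivityError(EstimationError):
    """A conditional law or weight is undefined: zero mass on the region,
    or fitted propensities incompatible with the requested estimand."""


class BinateWarning(UserWarning):
    """Base class for package warnings."""


class DegenerateArmWarning(BinateWarning):
    """All units fell on one side of the binarization cut-off."""


class SeparationWarning(BinateWarning):
    """A logistic fit reached fitted probabilities of 0 or 1."""


class FluctuationWarning(BinateWarning):
    """The TMLE targeting step failed; the estimator fell back to AIPW."""
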