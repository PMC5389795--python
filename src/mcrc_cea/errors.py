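"""Exception hierarchy for the cost-effectiveness model.

All model-facing errors derive from :class:`CEAError` so callers (and the
command-line layer) can distinguish configuration/validation problems from
genuine runtime failures.
"""


class CEAError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(CEAError):
    """A configuration file does not match the documented schema."""


class ValidationError(CEAError):
    """An input value violates a model invariant (e.g. probability > 1)."""


class InfeasibleStrategyError(ValidationError):
    """Transition probabilities of a strategy cannot form a stochastic row."""


class CalibrationError(CEAError):
    """Survival data cannot support a log-linear hazard fit."""


class UndefinedICERError(CEAError):
    """Incremental effectiveness is zero; an ICER is not defined."""


class BracketingError(CEAError):
    """A root search was asked to run on an interval with no sign change."""
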