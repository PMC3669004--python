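"""Exception hierarchy for the eelgrass leaf-growth pipeline."""


class EelgrassError(Exception):
    """Base class for all package errors."""


class AllometryDomainError(EelgrassError, ValueError):
    """An argument lies outside the domain of the allometric machinery
    (negative length, increment exceeding final length, ...)."""


class UnobservableRateError(EelgrassError):
    """The in situ rate needs dry weights at marking time, which field
    data cannot provide; use the allometric surrogate instead."""


class UndefinedIntervalError(EelgrassError):
    """No leaf appearance was observed, so the plastochrone interval is
    undefined."""


class MissingThirdLeafError(EelgrassError):
    """Skip-shoot signal: the shoot holds no rank-3 leaf, so it cannot
    contribute to the plastochrone mean or the bias decomposition."""


class EmptyCampaignError(EelgrassError):
    """A campaign mean was requested over an empty eligible set."""


class UnidentifiableModelError(EelgrassError):
    """The allometric fit is degenerate (e.g. all lengths equal)."""


class UndefinedCoefficientError(EelgrassError):
    """An agreement statistic is undefined for the given inputs
    (constant vectors, vanishing denominator)."""


class ValidationError(EelgrassError, ValueError):
    """Structured input (CSV table, config file) violated the schema; the
    message lists the offending rows or keys."""
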