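"""Exception hierarchy shared across the package."""


class MpRiskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MpRiskError, ValueError):
    """A scenario or model component is mis-specified (unknown family,
    unknown shape kind, unbound symbol, missing required shape...)."""


class ValidationError(MpRiskError, ValueError):
    """A parameter value violates an invariant; the message names the field."""


class InsufficientDataError(MpRiskError, ValueError):
    """Too few data points to perform a fit."""
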