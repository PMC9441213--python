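"""Exception hierarchy shared across the package."""


class SpeckleSenseError(Exception):
    """Base class for all package errors."""


class ValidationError(SpeckleSenseError, ValueError):
    """An argument or data structure violates a documented precondition."""


class DomainError(SpeckleSenseError, ValueError):
    """A physical parameter combination has no defined result
    (e.g. no guided evanescent field when n_eff <= n_s)."""


class ConfigurationError(SpeckleSenseError, ValueError):
    """An acquisition or run configuration is internally inconsistent
    (e.g. drive frequency at or above Nyquist)."""


class DegenerateDataError(SpeckleSenseError, ValueError):
    """Input data carries no usable signal (e.g. zero-variance sub-images
    in every grid cell of a frame stack)."""
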