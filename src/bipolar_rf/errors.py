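"""Exception hierarchy shared across the pipeline.

Input-contract violations raise :class:`InvalidInputError` (or a subclass);
numerical/degeneracy failures raise :class:`DegenerateError` subclasses so
callers can distinguish "fix your inputs" from "the data cannot support this".
"""


class BipolarRFError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BipolarRFError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(InvalidInputError):
    """A required column is missing or of the wrong shape."""


class ConfigError(InvalidInputError):
    """A configuration object is internally inconsistent."""


class DegenerateError(BipolarRFError, ValueError):
    """The data cannot support the requested computation."""


class DegenerateOutcomeError(DegenerateError):
    """Outcome vector contains a single class."""


class DegenerateGroupError(DegenerateError):
    """A comparison group is empty."""


class NoRootError(DegenerateError):
    """A bracketing search found no sign change."""


class SeparationWarning(UserWarning):
    """Quasi-complete separation detected during a logistic fit."""
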