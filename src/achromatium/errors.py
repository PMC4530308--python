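"""Exception taxonomy shared across the package.

All errors derive from ``ValueError`` so callers that only care about
"bad input" can catch one base class, while the CLI maps the subclasses
onto distinct exit codes.
"""


class AchromatiumError(ValueError):
    """Base class for all package-raised input/validation errors."""


class ValidityError(AchromatiumError):
    """A physical parameter is outside the validity range of a formulation."""


class InputError(AchromatiumError):
    """An input value or file violates a precondition."""


class AlignmentError(InputError):
    """Sequences are incompatible (e.g. unequal alignment lengths)."""


class UndefinedRatioError(InputError):
    """A requested ratio has a zero denominator."""


class ConfigError(AchromatiumError):
    """A run configuration is malformed (unknown keys, missing fields)."""
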