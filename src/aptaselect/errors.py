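"""Exception hierarchy for the toolkit.

All toolkit errors derive from :class:`AptaSelectError` so callers can catch
one base class; the CLI maps input-shaped errors to exit code 2 and fitting
failures to exit code 3.
"""


class AptaSelectError(Exception):
    """Base class for all toolkit errors."""


class InputError(AptaSelectError):
    """Invalid user-supplied value, table, or argument combination."""


class ParseError(InputError):
    """Malformed FASTA, Vienna, or tabular input."""


class AlphabetError(InputError):
    """A sequence contains characters outside {A, T, G, C}."""


class FlankError(InputError):
    """A sequence does not carry the expected constant flanks (strict mode)."""


class StructureError(InputError):
    """Unbalanced or ill-formed dot-bracket string."""


class ParameterError(InputError):
    """Physically meaningless parameter (non-positive f0, kd <= 0, ...)."""


class FitError(AptaSelectError):
    """Nonlinear fit failed to converge or data cannot constrain the model."""
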