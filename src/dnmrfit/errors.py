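"""Typed exceptions raised across the package.

Fitting code needs to distinguish malformed data from unphysical
parameters, so validation never silently clamps: it raises one of the
exception types below.
"""


class DnmrError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DnmrError, ValueError):
    """A parameter or data structure violates a physical invariant."""


class UndefinedPopulationError(ValidationError):
    """Equilibrium populations requested with k_ab = k_ba = 0."""


class ParseError(DnmrError, ValueError):
    """An input file is malformed; the message names file, line and column."""


class UnderdeterminedError(ValidationError):
    """Too few observations for the number of free parameters."""
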