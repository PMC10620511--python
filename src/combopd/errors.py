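"""Exception hierarchy.

All package errors derive from :class:`ComboPDError` so callers (and the CLI)
can catch one base class. ``DomainError`` subclasses ``ValueError`` because it
signals invalid numeric input; ``DataError`` signals malformed datasets;
``EstimationError`` signals an ill-posed fitting request (as opposed to a
fit that ran but failed to converge, which is reported via the results flag).
"""


class ComboPDError(Exception):
    """Base class for all combopd errors."""


class DomainError(ComboPDError, ValueError):
    """Invalid numeric input (negative concentration, non-positive psi, ...)."""


class DataError(ComboPDError):
    """Malformed or schema-violating dataset."""


class EstimationError(ComboPDError):
    """Ill-posed estimation request (no information for a free parameter)."""


class SolverError(ComboPDError):
    """ODE integration failure; carries solver diagnostics in the message."""
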