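"""Exception types shared across the package."""


class EFDAngioError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EFDAngioError, ValueError):
    """An argument violates a documented precondition."""


class OutOfDomainError(EFDAngioError, ValueError):
    """A position falls outside the cell or grid it was queried against."""


class NumericalError(EFDAngioError, ArithmeticError):
    """A numerical operation failed (singular matrix, iteration cap, ...)."""
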