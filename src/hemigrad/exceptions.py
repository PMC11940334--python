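"""Exception hierarchy.

Errors are split by origin so pipeline drivers can report whether a failure
came from user parameters, the data itself, numerical trouble, or calling
operations out of order.
"""


class HemigradError(Exception):
    """Base class for all package errors."""


class ParameterError(HemigradError, ValueError):
    """A user-supplied parameter is outside its documented range."""


class DataError(HemigradError, ValueError):
    """The input data violate a documented precondition."""


class NumericalError(HemigradError, ArithmeticError):
    """A numerical routine failed (non-PSD matrix, eigensolver, ...)."""


class StateError(HemigradError, RuntimeError):
    """An operation was called before its prerequisites (e.g. alignment)."""


class SelectionError(HemigradError, RuntimeError):
    """Feature selection produced an empty set; a fallback is advised."""
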