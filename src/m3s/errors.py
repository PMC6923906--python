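"""Typed exceptions raised across the package."""


class M3SError(Exception):
    """Base class for all package errors."""


class UnsupportedDataError(M3SError):
    """Data violates the support of the requested model (e.g. negative counts)."""


class InvalidParameterError(M3SError):
    """Model parameters violate their invariants."""


class NotConvergedError(M3SError):
    """An operation required a converged fit but received a non-converged one."""


class MatrixFormatError(M3SError):
    """Malformed input matrix: duplicate ids, dimension mismatch, NaN entries."""
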