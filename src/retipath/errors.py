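"""Exception hierarchy.

Errors are split by the contract they break: format (bad input file),
domain (bad numeric argument), configuration (inconsistent setup),
integrity (a structural invariant violated at run time).
"""


class RetipathError(Exception):
    """Base class for all package errors."""


class FormatError(RetipathError):
    """An input image or file violates the expected format."""


class DomainError(RetipathError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ConfigurationError(RetipathError):
    """A configuration is internally inconsistent or incomplete."""


class IntegrityError(RetipathError):
    """A structural invariant (e.g. radial symmetry) is violated."""


class ShapeError(RetipathError, ValueError):
    """Array operands have incompatible shapes."""
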