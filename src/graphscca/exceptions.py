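"""Exception hierarchy shared across the package."""


class GraphSccaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GraphSccaError, ValueError):
    """Invalid input data, parameters, or configuration."""


class NumericalError(GraphSccaError, ArithmeticError):
    """A numerical routine failed (singular system, non-finite objective, ...)."""


class ParseError(GraphSccaError, ValueError):
    """A file could not be parsed; the message locates the offending cell/line."""
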