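"""Exception taxonomy shared across the package."""


class SwarmgateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SwarmgateError, ValueError):
    """A file could not be parsed under the requested format."""


class SchemaError(SwarmgateError, ValueError):
    """Structurally valid input that violates the expected schema
    (missing label column, channel mismatch, absent labels)."""


class ParseError(FormatError):
    """A non-numeric cell or malformed record; carries row/column context."""


class ConvergenceError(SwarmgateError, RuntimeError):
    """An iterative solver failed to converge.

    The default SVM path prefers returning its best feasible iterate with
    a warning over raising; this class is available for strict callers.
    """

    def __init__(self, message: str, n_iterations: int):
        super().__init__(message)
        self.n_iterations = n_iterations


class FitnessError(SwarmgateError, RuntimeError):
    """An objective function returned a non-finite value; names the position."""
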