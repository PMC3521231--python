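"""Exception hierarchy shared across the package.

Each error class carries the process exit code the command-line front end
uses when the error escapes to the top level.
"""


class CfmdsError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(CfmdsError):
    """Malformed input data (shape, symmetry, sign, missing values)."""

    exit_code = 2


class ParameterError(CfmdsError):
    """Inconsistent or out-of-range user parameters (m, p, s, budget)."""

    exit_code = 2


class NumericError(CfmdsError):
    """Numerically undefined result, e.g. no positive eigenvalue to embed on."""

    exit_code = 3


class MdsWarning(UserWarning):
    """Recoverable numerical issue (negative eigenvalues clamped, large residual)."""
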