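"""Exception hierarchy shared by all maic modules.

Every error raised by the package derives from :class:`MaicError`, so callers
(and the CLI) can map failures to stable diagnostic categories.
"""

from __future__ import annotations


class MaicError(Exception):
    """Base class for all errors raised by maic."""


class SchemaError(MaicError):
    """An input file does not match the declared column schema."""


class ParseError(SchemaError):
    """A cell could not be parsed as the expected type."""


class ConfigError(MaicError):
    """A configuration value is invalid or inconsistent."""


class DataError(MaicError):
    """Input data violate a structural requirement (missingness, arm counts,
    constant covariates, degenerate weight mass)."""


class FeasibilityError(DataError):
    """No nonnegative weight vector can satisfy the moment constraints,
    e.g. a target mean outside the observed covariate range."""


class NumericError(MaicError):
    """A computation produced a non-finite value despite overflow guards."""


class UsageError(MaicError):
    """An operation was called with an unsupported argument combination."""


class ConvergenceError(MaicError):
    """The weight solver did not reach the requested tolerance.

    Carries the best iterate found so callers can inspect the near-solution.
    """

    def __init__(self, message: str, solution=None):
        super().__init__(message)
        self.solution = solution
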