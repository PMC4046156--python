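"""Exception hierarchy for nucmir.

Every error raised on a contract violation derives from :class:`NucmirError`
so callers can catch pipeline failures without masking programming errors.
"""


class NucmirError(Exception):
    """Base class for all nucmir errors."""


class SchemaError(NucmirError):
    """Input table/sample-sheet is structurally invalid (missing metadata, bad header)."""


class ValidationError(NucmirError):
    """A value violates its domain contract (CT out of range, bad alphabet, ...)."""


class UndefinedResultError(NucmirError):
    """An operation was asked to produce a value that is undefined for its inputs
    (e.g. a fold change from an undetermined CT)."""


class InsufficientDataError(NucmirError):
    """Not enough observations to run the requested statistic."""


class ConfigurationError(NucmirError):
    """Inconsistent or impossible configuration (mismatched comparisons, empty
    control set, fewer than two cell types, infeasible simulation)."""


class QCError(NucmirError):
    """Fraction quality control cannot be evaluated (missing marker class) or
    failed under --strict."""


class DegeneratePriorError(NucmirError):
    """Empirical-Bayes prior cannot be estimated (e.g. all gene variances zero)."""
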