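"""Exception hierarchy.

All library errors derive from :class:`ConnAuditError` so callers can catch
one base class at CLI or pipeline boundaries.
"""


class ConnAuditError(Exception):
    """Base class for all connaudit errors."""


class InvalidParcellationError(ConnAuditError):
    """Parcel count does not define a valid edge space (p < 2)."""


class EdgeIndexError(ConnAuditError, IndexError):
    """Region pair or edge id outside the upper-triangle index range."""


class FormatError(ConnAuditError):
    """A file's shape or layout disagrees with the manifest declaration."""


class DataError(ConnAuditError):
    """Inconsistent cohort data (duplicate subject ids, misalignment)."""


class QueryError(ConnAuditError):
    """Subgroup query references unknown columns or cannot be evaluated."""


class DegenerateDesignError(ConnAuditError):
    """Rank-deficient or undersized regression design."""


class DegeneratePhenotypeError(ConnAuditError):
    """Phenotype has zero variance (or too few complete cases) to correlate."""


class SingularCovarianceError(ConnAuditError):
    """Regularized covariance is not positive definite; raise the shrinkage."""


class IncompatibleMapsError(ConnAuditError):
    """Maps or feature spaces with mismatched size, scale, or ids."""


class EmptyGroupError(ConnAuditError):
    """A group mask selects no subjects."""


class RequestError(ConnAuditError):
    """A request parameter (k, n_components, ...) exceeds what the data has."""


class SpecError(ConnAuditError):
    """Invalid synthetic-cohort specification."""
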