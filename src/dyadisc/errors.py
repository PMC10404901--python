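"""Exception hierarchy for the dyadic-ISC pipeline.

Every error raised by this package derives from :class:`DyadISCError` so that
callers can catch pipeline problems without masking programming errors.
"""


class DyadISCError(Exception):
    """Base class for all errors raised by dyadisc."""


class ValidationError(DyadISCError, ValueError):
    """Invalid configuration or input values."""


class DimensionError(ValidationError):
    """A matrix does not have the expected shape (e.g. wrong parcel count)."""


class ParseError(ValidationError):
    """A delimited time-series file contains a non-numeric or non-finite cell."""


class MissingRunError(DyadISCError, KeyError):
    """A requested run is not among a subject's available runs."""


class DegenerateSeriesError(DyadISCError):
    """A time series has zero variance; carries subject and parcel identifiers."""

    def __init__(self, subject_id, parcel, message=None):
        self.subject_id = subject_id
        self.parcel = parcel
        super().__init__(
            message
            or f"zero-variance time series for subject {subject_id!r}, parcel {parcel!r}"
        )


class DegenerateParcelError(DyadISCError):
    """A parcel's ISC values are constant across dyads and cannot be z-scored."""

    def __init__(self, parcels, message=None):
        self.parcels = list(parcels)
        super().__init__(
            message or f"constant ISC column(s) in parcel(s): {self.parcels}"
        )


class DegenerateCovariateError(DyadISCError):
    """A continuous model column has zero variance."""


class MissingDataError(DyadISCError):
    """A required subject-level value (e.g. a demographic field) is missing."""


class UnknownSubjectError(DyadISCError, KeyError):
    """An edge list or dyad references a subject absent from the subject table."""


class DuplicateDyadError(DyadISCError):
    """The canonical (i < j) dyad table contains a repeated pair."""


class SingularDesignError(DyadISCError):
    """The fixed-effects design matrix is rank deficient."""

    def __init__(self, aliased, message=None):
        self.aliased = list(aliased)
        super().__init__(
            message or f"rank-deficient design; aliased column(s): {self.aliased}"
        )


class NotConvergedError(DyadISCError):
    """REML optimisation did not converge; contrasts are refused."""


class InsufficientDataError(DyadISCError):
    """Fewer unique observations than fixed effects (N_unique <= k)."""
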