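"""Exception hierarchy for fcreg."""


class FcregError(Exception):
    """Base class for all fcreg errors."""


class DomainError(FcregError):
    """Evaluation requested outside the spline domain (no silent extrapolation)."""


class DegenerateKnotsError(FcregError):
    """Too few distinct time points to place the requested interior knots."""


class InvalidPenaltyError(FcregError):
    """Difference-penalty order incompatible with the basis dimension."""


class RankDeficiencyError(FcregError):
    """Singular normal equations / penalized information matrix."""


class SingularityError(FcregError):
    """Singular kernel matrix in BLUP conditioning (e.g. zero nugget with tied times)."""


class IdentifiabilityError(FcregError):
    """Covariance cannot be identified (no off-diagonal residual pairs)."""


class MissingDataError(FcregError):
    """A required covariate value or model is missing."""


class ExtrapolationError(FcregError):
    """Prediction requested beyond the latest training observation time T_max."""


class ConfigurationError(FcregError):
    """Inconsistent user configuration (e.g. prediction window before its cutoff)."""


class SelectionError(FcregError):
    """Smoothing-parameter selection criterion was non-finite on the whole grid."""
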