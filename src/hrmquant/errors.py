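"""Exception hierarchy for hrmquant."""


class HrmQuantError(Exception):
    """Base class for all hrmquant errors."""


class InvalidCoordinateError(HrmQuantError):
    """An ATG-relative coordinate is zero or otherwise out of convention."""


class PatternMismatchError(HrmQuantError):
    """A methylation pattern does not match the CpG count of the sequence."""


class UnmappedPrimerError(HrmQuantError):
    """A primer could not be located on the template (genomic or converted)."""


class NormalizationError(HrmQuantError):
    """Melt-curve baseline normalization failed (bad windows or collapsed span)."""


class CalibrationError(HrmQuantError):
    """Standard-curve fit is impossible or degenerate."""


class UndefinedStatisticError(HrmQuantError):
    """A statistic (ROC AUC, log-rank, correlation) is undefined on this input."""


class CohortFormatError(HrmQuantError):
    """A cohort or melt table violates the expected schema."""
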