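"""Exception types shared across the package."""


class ToxtempoError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ToxtempoError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class StudyError(ToxtempoError, ValueError):
    """An expression study violates a structural invariant (alignment,
    missing matched control, missing values, ...)."""


class StudyFormatError(ToxtempoError, ValueError):
    """An on-disk study directory is malformed; the message points at the
    file and, where possible, the row involved."""


class GmtParseError(ToxtempoError, ValueError):
    """A GMT gene-set file is malformed; the message names the line number."""


class DesignError(ToxtempoError, ValueError):
    """A regression design matrix is unusable (rank deficient, too few
    observations, degree too high for the number of time points, ...)."""
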