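"""Exception hierarchy for splitmr."""


class SplitMRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SplitMRError, ValueError):
    """Invalid simulation or study configuration."""


class DegenerateDesignError(SplitMRError, ValueError):
    """Regression design matrix is rank deficient or under-determined."""


class SeparationError(SplitMRError, RuntimeError):
    """Logistic likelihood maximization diverged (quasi-complete separation)."""


class EstimationError(SplitMRError, ValueError):
    """Summary-statistic MR estimator cannot be computed from the inputs."""


class ClumpingError(SplitMRError, ValueError):
    """Clumping input is incomplete (missing position or reference genotypes)."""


class StudyError(SplitMRError, RuntimeError):
    """Study-level failure, e.g. no usable iteration produced an instrument set."""
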