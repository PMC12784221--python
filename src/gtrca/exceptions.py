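"""Named exceptions raised across the package."""


class GtrcaError(Exception):
    """Base class for all package-specific errors."""


class ZeroVarianceChannelError(GtrcaError):
    """A channel has zero variance over the concatenated epochs and cannot be standardized."""

    def __init__(self, subject_id, channels):
        self.subject_id = subject_id
        self.channels = list(channels)
        super().__init__(
            f"subject {subject_id!r}: zero-variance channel(s) {self.channels}; "
            "standardization to unit variance is undefined"
        )


class TooFewTrialsError(GtrcaError):
    """Within-subject reproducibility needs at least two trials."""


class EpochMismatchError(GtrcaError):
    """Subjects do not share epoch length and/or sampling rate."""


class RankDeficiencyError(GtrcaError):
    """Dimensionality regularization left no usable directions, or Q is singular."""


class EigendecompositionError(GtrcaError):
    """The generalized eigenvalue solve produced non-finite eigenvalues.

    Usually a symptom of a (near-)singular covariance; lower the retained
    variance fraction of the regularization.
    """


class LatencyOverflowError(GtrcaError):
    """Planted component latencies do not fit inside the epoch."""


class CovarianceNotSPDError(GtrcaError):
    """The requested noise covariance is not symmetric positive definite."""


class UnknownFormatError(GtrcaError):
    """File extension not recognized by the epoch readers."""
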