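"""Exception hierarchy for the pipeline."""


class SexKaryoError(Exception):
    """Base class for all package errors."""


class ContigMismatchError(SexKaryoError):
    """A configured contig is absent from a BAM/VCF header."""


class MissingIndexError(SexKaryoError):
    """A BAM lacks the index required for region queries."""


class EmptyAlignmentError(SexKaryoError):
    """No high-quality mapped reads: fractions are undefined."""


class UnknownSampleError(SexKaryoError):
    """A requested sample is not present in the VCF."""


class UndefinedRatioError(SexKaryoError):
    """Xmap and Ymap are both zero; their ratio is undefined."""


class ConfigurationError(SexKaryoError):
    """A requested feature or option cannot be satisfied by the inputs."""


class DegenerateFeatureError(SexKaryoError):
    """A selected feature has zero variance and cannot be scaled."""


class ConvergenceError(SexKaryoError):
    """EM failed to produce a finite fit across all restarts."""

    def __init__(self, message: str, traces=None):
        super().__init__(message)
        self.traces = traces or []


class LabelingError(SexKaryoError):
    """No feature separates the two cluster means; sexes cannot be named."""


class InsufficientCohortError(SexKaryoError):
    """Fewer than two usable samples in a sex stratum."""
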