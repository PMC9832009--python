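"""Exception hierarchy shared across the pipeline."""


class DnbtrackError(Exception):
    """Base class for all dnbtrack errors."""


class FormatError(DnbtrackError):
    """Malformed input file or in-memory table (duplicates, negatives, bad shape)."""


class NormalizationError(DnbtrackError):
    """Size-factor estimation impossible (e.g. a sample with all-zero counts)."""


class ConfigError(DnbtrackError):
    """Invalid configuration value or inconsistent parameter combination."""


class InsufficientReplicatesError(DnbtrackError):
    """A time point has too few replicates for correlation estimation.

    Callers hitting this on `dnb_scan` should use `sliding_window_scan`,
    which pools replicates of consecutive time points.
    """


class AnalysisError(DnbtrackError):
    """A stage's mathematical preconditions are not met (empty groups, missing genes...)."""
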