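"""Exception hierarchy for the MVCS analysis pipeline.

Unusable-data conditions (an all-censored run, an empty ROI, a too-short
run pair) are signalled with dedicated exceptions so that callers can
drop the affected record and keep going, mirroring how the analysis
tolerates incomplete datasets.
"""


class MvcsError(Exception):
    """Base class for all package errors."""


class ConfigError(MvcsError, ValueError):
    """Invalid configuration value; message names the offending field."""


class RunUnusableError(MvcsError):
    """A run cannot be analyzed (e.g. every volume was censored)."""


class RoiUnusableError(MvcsError):
    """An ROI cannot be analyzed (e.g. no voxel passed GM selection)."""


class PairUnusableError(MvcsError):
    """A run pair cannot be analyzed (e.g. too few matched volumes)."""


class DegenerateCorrelationError(MvcsError):
    """A correlation reached |r| >= 1 where a finite Fisher z is required."""


class DegenerateSimilarityError(DegenerateCorrelationError):
    """Two MVCS matrices are perfectly (anti)correlated; SI is undefined."""
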