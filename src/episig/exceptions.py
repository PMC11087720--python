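"""Exception hierarchy for the episignature pipeline.

Every error raised by the package derives from :class:`EpisigError` so
callers can catch pipeline failures without masking programming errors.
"""


class EpisigError(Exception):
    """Base class for all pipeline errors."""


class FormatError(EpisigError, ValueError):
    """Malformed tabular input (duplicate ids, out-of-range or non-numeric cells)."""


class ArgumentError(EpisigError, ValueError):
    """Invalid argument value for an operation."""


class ConsistencyError(EpisigError, ValueError):
    """Internally inconsistent inputs (e.g. a planted effect with no direction)."""


class MatchingError(EpisigError):
    """Control matching failed; carries the unmatched case ids."""

    def __init__(self, message: str, unmatched: list[str] | None = None):
        super().__init__(message)
        self.unmatched = list(unmatched or [])


class ModelError(EpisigError):
    """Per-probe regression could not be fit (e.g. rank-deficient design)."""


class DegenerateVarianceError(EpisigError):
    """All residual variances are zero; the variance prior is undefined."""


class SelectionError(EpisigError):
    """No probe survives the selection filters."""


class InstabilityError(EpisigError):
    """Case pruning flagged more than half the cases in one round."""


class SplitError(EpisigError):
    """A stratum is too small to contribute to both train and test splits."""


class TrainingError(EpisigError):
    """Classifier training failed (e.g. a single-class label vector)."""


class ScoringError(EpisigError):
    """A sample cannot be scored; carries the missing probe ids."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = list(missing or [])


class AnnotationError(EpisigError):
    """Probes absent from the annotation table."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = list(missing or [])
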