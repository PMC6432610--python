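"""Exception hierarchy for the vidsleep pipeline.

All pipeline errors derive from :class:`VidsleepError` so callers (and the
CLI) can distinguish categorized pipeline failures from programming errors.
"""


class VidsleepError(Exception):
    """Base class for all vidsleep pipeline errors."""


class InvalidInputError(VidsleepError, ValueError):
    """Malformed or inconsistent input data (shapes, labels, lengths)."""


class InsufficientFramesError(InvalidInputError):
    """Fewer than two frames: motion estimation is undefined."""


class InsufficientDataError(InvalidInputError):
    """Signal too short to cover a single epoch."""


class UnderdeterminedModelError(VidsleepError):
    """A class has too few samples to estimate the discriminant model."""


class UndefinedMetricError(VidsleepError):
    """A requested metric has no defined value (e.g. single-class AUC)."""


class InvalidConfigError(VidsleepError, ValueError):
    """Configuration values that are out of range or mutually inconsistent."""


class HypnogramParseError(InvalidInputError):
    """A hypnogram file failed validation; message cites the offending line."""
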