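"""Exception types shared across the package."""


class SongdriftError(Exception):
    """Base class for package errors."""


class InvalidSpecError(SongdriftError, ValueError):
    """A subunit specification is malformed (e.g. no segments)."""


class ConfigError(SongdriftError, ValueError):
    """A stimulus/pipeline configuration is malformed."""


class UnknownLabelError(SongdriftError, KeyError):
    """A subunit label cannot be resolved in the catalog or weight map."""


class UndefinedRatioError(SongdriftError, ZeroDivisionError):
    """A metric ratio is undefined (zero denominator)."""


class UnreachableThresholdError(SongdriftError, ValueError):
    """Weight and threshold have opposite signs: the drift never reaches it."""


class EmptyCohortError(SongdriftError, RuntimeError):
    """Every synthetic female was excluded by the control criterion."""
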