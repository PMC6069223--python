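"""Exception hierarchy shared across the package."""


class TrajkinError(Exception):
    """Base class for all trajkin errors."""


class ParseError(TrajkinError):
    """A file could not be parsed; the message names the offending line."""


class FormatError(TrajkinError):
    """A file parsed but violates the format contract (e.g. mixed frequencies)."""


class DataQualityError(TrajkinError):
    """Data violates a quality contract (gaps too long, missing values)."""


class CalibrationError(TrajkinError):
    """Segment-length calibration could not be completed."""


class ModelError(TrajkinError):
    """Kinematic model construction failed (missing joints, degenerate frame)."""


class FeatureError(TrajkinError):
    """A trajectory does not satisfy the preconditions of a feature computation."""


class ScoringError(TrajkinError):
    """Scoring or aggregation could not be performed."""


class RecipeError(TrajkinError):
    """A synthetic-motion recipe is invalid or unreachable."""
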