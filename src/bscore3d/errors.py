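"""Exception taxonomy shared across the package.

Every error a pipeline stage can raise deliberately derives from
:class:`BScoreError` so callers (the cohort runners, the CLI) can convert
failures into per-record exclusion entries instead of aborting a batch —
mirroring how clinical pipelines account for excluded scans rather than
silently dropping them.
"""


class BScoreError(Exception):
    """Base class for all deliberate errors raised by this package."""


class MeshFormatError(BScoreError):
    """A mesh file could not be parsed (message names the byte offset)."""


class UnsupportedTopologyError(BScoreError):
    """Mesh contains non-triangular faces or otherwise unusable topology."""


class WatertightnessError(BScoreError):
    """Operation requires a watertight mesh (message lists boundary-edge count)."""


class ZeroAreaError(BScoreError):
    """A vertex has no incident faces / zero-area star; normals undefined."""


class DegenerateFieldError(BScoreError):
    """Distance field requested on an all-empty or all-occupied volume."""


class CorrespondenceError(BScoreError):
    """Shape-space arithmetic attempted across different parameterizations."""


class RankError(BScoreError):
    """A shape is degenerate (all points coincident); alignment undefined."""


class InsufficientDataError(BScoreError):
    """Too few shapes/records for the requested statistic or model."""


class ConvergenceError(BScoreError):
    """An iterative fit diverged (residual increased repeatedly)."""


class OutOfFieldError(BScoreError):
    """Target anatomy lies (partly) outside the imaged volume; fit impossible."""


class DegenerateAxisError(BScoreError):
    """Healthy and OA mean shapes coincide; no direction can be defined."""


class DegenerateSpreadError(BScoreError):
    """Healthy projections have zero spread; the z-score unit is undefined."""


class UndefinedStatisticError(BScoreError):
    """A statistic's denominator is identically zero (e.g. two equal constants)."""


class DegenerateRegressionError(BScoreError):
    """Regression on a constant predictor."""


class ConfigError(BScoreError):
    """Invalid configuration value (mixture not summing to 1, bad spacing, ...)."""


class ManifestError(BScoreError):
    """A CSV manifest is malformed (message names the row or column)."""
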