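"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PigSDMError` carrying enough context
(watershed id, polygon id, column name) to locate the offending entity.
"""


class PigSDMError(Exception):
    """Base class for all package errors."""


class ConfigError(PigSDMError):
    """Invalid or unknown configuration value."""


class ShapeError(PigSDMError):
    """Mismatched grid/array shapes between inputs."""


class NoCoverageError(PigSDMError):
    """No weather station within the search radius of a watershed centroid."""


class NoWaterError(PigSDMError):
    """No retained water cell anywhere on the grid after the flow filter."""


class ConstantColumnError(PigSDMError):
    """A covariate column is constant on the standardization sample."""


class GeometryError(PigSDMError):
    """An occurrence polygon has invalid geometry."""


class ScaleError(PigSDMError):
    """Covariates supplied on the wrong (unstandardized) scale."""


class DegenerateBinningError(PigSDMError):
    """Predictions cannot be split into at least two non-empty bins."""


class SampleSizeError(PigSDMError):
    """Requested sample exceeds the available watershed pool."""
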