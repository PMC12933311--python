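"""Exception hierarchy shared by all pipeline stages."""


class IvoctregError(Exception):
    """Base class for all package-specific errors."""


class InvalidContourError(IvoctregError, ValueError):
    """A lumen contour is degenerate (too few points or zero area)."""


class InvalidPullbackError(IvoctregError, ValueError):
    """A pullback violates its structural invariants."""


class ParameterError(IvoctregError, ValueError):
    """A configuration or algorithm parameter is out of range."""


class SchemaError(IvoctregError, ValueError):
    """A serialized pullback or config document fails validation."""


class UndefinedMetricError(IvoctregError, ValueError):
    """An agreement statistic is undefined for the given inputs."""


class PhantomConfigError(IvoctregError, ValueError):
    """Phantom construction is infeasible under the given configuration."""
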