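"""Exception hierarchy shared across the package."""


class EcoevoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EcoevoError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(EcoevoError):
    """An input table violates its declared schema or invariants."""


class DesignError(EcoevoError):
    """A statistical design is degenerate (empty cell, rank deficiency, too few levels)."""


class DegenerateTrajectoryError(EcoevoError):
    """A trajectory has no usable direction or shape (zero variance / zero size)."""
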