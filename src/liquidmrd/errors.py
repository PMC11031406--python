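"""Exception hierarchy shared across the pipeline."""


class LiquidMRDError(Exception):
    """Base class for all package errors."""


class SchemaError(LiquidMRDError):
    """A table is missing a mandatory column or uses an unknown label."""


class ValidationError(LiquidMRDError):
    """A parsed value violates a documented invariant."""


class EvaluationError(LiquidMRDError):
    """A rule could not be evaluated for lack of required inputs."""


class CalibrationError(LiquidMRDError):
    """Numerical prior calibration failed to find a root."""
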