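"""Exception hierarchy shared by all pipeline stages."""


class OptofluxError(Exception):
    """Base class for all package errors."""


class DataError(OptofluxError):
    """Malformed or out-of-contract input data (non-positive ratios, bad shapes...)."""


class CalibrationError(OptofluxError):
    """A calibration fit failed, is degenerate, or violates monotonicity."""


class GeometryError(OptofluxError):
    """Scene or layout geometry violates its invariants (overlaps, out of bounds)."""


class ConfigurationError(OptofluxError):
    """Run or simulation configuration cannot be satisfied (stability, unknown keys)."""


class SamplingError(OptofluxError):
    """Stochastic placement failed after the bounded number of retries."""
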