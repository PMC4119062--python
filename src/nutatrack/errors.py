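"""Exception hierarchy for nutatrack."""


class NutatrackError(Exception):
    """Base class for all package errors."""


class FormatError(NutatrackError):
    """A file does not have the expected structure (missing columns, bad header)."""


class DataError(NutatrackError):
    """File structure is fine but a value is invalid (non-monotone timestamps, NaN)."""


class ConfigError(NutatrackError):
    """A calibration or generator configuration violates its invariants."""


class StateError(NutatrackError):
    """An operation was applied to data in the wrong unit system or frame."""


class FitError(NutatrackError):
    """Ellipse fitting failed (too few points, degenerate scatter, non-elliptic solution)."""
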