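"""Exception hierarchy shared across the package."""


class VgxeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VgxeError):
    """Invalid configuration values (counts, ranges, fractions)."""


class SimulationError(VgxeError):
    """Numerical failure while generating synthetic data."""


class InputValidationError(VgxeError):
    """Malformed input data: bad schema, out-of-range values, duplicates."""


class EstimationError(VgxeError):
    """Model fitting failed in a way that cannot be reported as a result."""
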