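"""Exception hierarchy shared across the package."""


class SepsisRLError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SepsisRLError, ValueError):
    """Invalid simulation or model parameter."""


class ParseError(SepsisRLError, ValueError):
    """Malformed cohort or pool file; message names row and column."""


class ConfigurationError(SepsisRLError, ValueError):
    """Inconsistent configuration (unknown variable, bad limits, overlapping regions)."""


class ImputationError(SepsisRLError, ValueError):
    """KNN imputation cannot proceed; message names the offending column."""


class ContractError(SepsisRLError, ValueError):
    """Caller violated an operation contract (shape/dimension/flag mismatch)."""


class TrainingError(SepsisRLError, RuntimeError):
    """Training diverged; message carries the step index."""
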