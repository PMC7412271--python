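"""Exception hierarchy shared across the package."""


class MKLSelectError(Exception):
    """Base class for all package errors."""


class StructuralError(MKLSelectError):
    """Shape/ordering inconsistencies between sources or datasets."""


class LabelError(MKLSelectError):
    """Labels outside {-1, +1} or a missing class."""


class SplitError(MKLSelectError):
    """Train/test partitioning cannot satisfy its constraints."""


class ConfigError(MKLSelectError):
    """Invalid configuration values."""


class ParameterError(MKLSelectError):
    """Out-of-range numeric parameter (K, bandwidths, counts)."""


class StateError(MKLSelectError):
    """Operation invoked on an object lacking required state."""


class DegenerateModelError(MKLSelectError):
    """Training collapsed (all-zero kernels or kernel weights)."""
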