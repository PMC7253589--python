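"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Inconsistent or invalid configuration."""


class ShapeError(ValueError):
    """Array shapes or channel counts do not match."""


class DataError(ValueError):
    """Input data violate a contract (non-finite values, unknown labels, ...)."""


class AlignmentError(ValueError):
    """Image and label grids are not aligned."""
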