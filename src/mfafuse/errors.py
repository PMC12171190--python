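"""Exception hierarchy used across the package."""


class MFAFuseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MFAFuseError):
    """Invalid configuration value or file."""


class ContractError(MFAFuseError):
    """An operation was called with arguments violating its contract
    (shape mismatch, off-simplex weights, non-binary masks, ...)."""


class DegenerateInputError(MFAFuseError):
    """Input carries no usable signal (e.g. a constant image passed to a
    normalizer that divides by its spread)."""
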