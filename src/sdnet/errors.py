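"""Exception hierarchy shared across the package."""


class SDNetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SDNetError, ValueError):
    """An invalid configuration value (names the offending field)."""


class ContractError(SDNetError, ValueError):
    """A call-contract violation (shape mismatch, non-binary mask, ...)."""


class ShapeError(ContractError):
    """Array shapes incompatible with the requested operation."""


class NonBinaryMaskError(ContractError):
    """A mask contained values outside {0, 1}."""


class NotAVolumeError(ContractError):
    """A file did not hold a 3D scalar image."""


class TrainingError(SDNetError, RuntimeError):
    """Training cannot proceed (e.g. empty labeled set)."""


class EvaluationError(SDNetError, RuntimeError):
    """Evaluation cannot proceed (e.g. empty test set)."""
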