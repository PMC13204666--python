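"""Package-level exception types."""


class InvalidInputError(ValueError):
    """Raised when an operation receives data violating its preconditions."""


class ConfigurationError(ValueError):
    """Raised when a model or training configuration is inconsistent."""


class StratificationError(ValueError):
    """Raised when a stratified split is infeasible (a class is too small)."""


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""
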