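"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a model, network or protocol configuration is invalid."""


class DaleViolationError(ConfigurationError):
    """Raised when a requested weight configuration would need a negative
    inhibitory magnitude (violating Dale's principle)."""


class BranchInconsistencyError(RuntimeError):
    """Raised when a linear steady-state solution contradicts the assumed
    rectification branch assignment."""


class DivergenceError(RuntimeError):
    """Raised when population rates exceed the configured cap during training."""
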