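"""Exception types shared across the package."""


class MobceaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MobceaError):
    """A model configuration document is structurally invalid."""


class DomainError(MobceaError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class FitError(MobceaError):
    """A distribution fit failed to converge or bracket a solution."""
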