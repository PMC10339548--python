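"""Exception hierarchy shared across the package."""


class NomostackError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NomostackError):
    """A rule, feature name, or config value does not match the data."""


class ValidationError(NomostackError, ValueError):
    """An input violates an operation's precondition."""


class EmptyCohortError(NomostackError):
    """No patient rows survived reading/quality control."""


class StratificationError(NomostackError):
    """A stratum is too small (or a class is missing) for the requested split/CV."""


class ConvergenceError(NomostackError):
    """An iterative fit failed to converge (e.g. separation in ordinal regression)."""
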