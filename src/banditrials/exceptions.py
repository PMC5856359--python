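"""Exception types shared across the package."""


class BanditrialsError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BanditrialsError, ValueError):
    """A parameter lies outside its admissible range (e.g. discount >= 1)."""


class UndefinedStateError(BanditrialsError, ValueError):
    """A quantity was requested for a state where it is undefined.

    The improper uniform prior yields no posterior (and no index) before an
    arm has at least one observation; callers must go through the
    initialization rule instead.
    """


class ConvergenceError(BanditrialsError, RuntimeError):
    """A numerical routine failed its self-consistency / convergence check."""


class ConfigurationError(BanditrialsError, ValueError):
    """A rule or study configuration is inconsistent or incomplete."""
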