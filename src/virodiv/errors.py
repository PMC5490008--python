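"""Exception hierarchy shared by all pipeline stages."""


class VirodivError(Exception):
    """Base class for all package errors."""


class InputError(VirodivError, ValueError):
    """Invalid user input (bad alphabet, empty sequence, out-of-range parameter)."""


class ConfigurationError(VirodivError, ValueError):
    """Mutually inconsistent configuration options."""


class DivergenceError(VirodivError):
    """Two sequences are too divergent for the requested comparison."""


class ConvergenceError(VirodivError):
    """Iterative calibration failed to reach its target."""


class ConsistencyError(VirodivError):
    """Cross-referenced records disagree (e.g. a hit naming an unknown genome)."""


class UndefinedStatisticError(VirodivError, ZeroDivisionError):
    """A ratio statistic whose denominator is empty or zero."""
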