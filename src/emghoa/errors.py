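"""Exception hierarchy shared across the pipeline stages."""


class EmghoaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EmghoaError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SignalLengthError(EmghoaError, ValueError):
    """A signal is too short for the requested operation."""


class MissingDataError(EmghoaError, KeyError):
    """Required recordings/tasks are absent for a participant."""


class NormalizationError(EmghoaError, ValueError):
    """A normalization denominator is non-positive."""


class MissingInputError(EmghoaError, KeyError):
    """A classifier input variable is absent; the message names it."""


class StatisticsError(EmghoaError, ValueError):
    """A statistical routine received data violating its preconditions."""
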