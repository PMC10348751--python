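"""Exception hierarchy for medspace."""


class MedspaceError(Exception):
    """Base class for all medspace errors."""


class ParameterError(MedspaceError, ValueError):
    """An operation was called with an invalid parameter value."""


class ConfigurationError(MedspaceError, ValueError):
    """A configuration file or override set is invalid.

    Carries the offending key names in ``keys`` when known.
    """

    def __init__(self, message, keys=()):
        super().__init__(message)
        self.keys = tuple(keys)


class IntegrationError(MedspaceError, RuntimeError):
    """The integrator produced non-finite fields.

    Carries diagnostic context: the simulation time and, for spatial runs,
    the grid index where the first non-finite value appeared.
    """

    def __init__(self, message, t=None, where=None):
        super().__init__(message)
        self.t = t
        self.where = where
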