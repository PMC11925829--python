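"""Exception types shared across the engine."""


class RuleChoiceError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(RuleChoiceError, ValueError):
    """A schedule or agent parameter is outside its valid range."""


class ProtocolError(RuleChoiceError):
    """An operation was attempted outside the phase/component that allows it."""


class PhaseNotApplicableError(ProtocolError):
    """A phase was requested that the configured experiment does not include."""


class ConfigError(RuleChoiceError):
    """A configuration file failed schema validation.

    ``keys`` lists the offending configuration keys, when known.
    """

    def __init__(self, message: str, keys: list[str] | None = None):
        super().__init__(message)
        self.keys = keys or []
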