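"""Exception hierarchy shared across the pipeline."""


class HubnetError(Exception):
    """Base class for all hubnet errors."""


class ParseError(HubnetError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ConfigurationError(HubnetError, ValueError):
    """An unknown dialect, metric or out-of-range parameter was supplied."""


class ValidationError(HubnetError, ValueError):
    """Input data violate a documented precondition."""
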