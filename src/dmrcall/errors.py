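"""Exception hierarchy shared across the pipeline."""


class DmrcallError(Exception):
    """Base class for all errors raised by dmrcall."""


class ParseError(DmrcallError):
    """A text input could not be parsed; the message names the offending line."""


class ValidationError(DmrcallError):
    """Parsed data violates an invariant (negative count, empty interval, ...)."""


class ConfigurationError(DmrcallError):
    """Inconsistent or impossible parameters (empty arm, k_min > n groups, ...)."""


class UndefinedRatioError(DmrcallError):
    """Methylation ratio requested at a site with zero total coverage."""
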