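"""Exception types shared across the package."""


class MethleakError(Exception):
    """Base class for package errors."""


class ConfigurationError(MethleakError):
    """A design or pipeline configuration is invalid; names the offending field."""


class ParseError(MethleakError):
    """A file could not be parsed; carries the offending line number when known."""


class UndefinedFitError(MethleakError):
    """A regression fit is undefined (constant predictor or response)."""
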