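"""Exception hierarchy for the pipeline."""


class IbcpipeError(Exception):
    """Base class for all package errors."""


class ConfigError(IbcpipeError):
    """Invalid configuration; the message names the offending field."""


class FormatError(IbcpipeError):
    """A file failed to parse or lacked required fields."""


class DomainError(IbcpipeError):
    """Inputs violate a precondition of an analysis operation."""
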