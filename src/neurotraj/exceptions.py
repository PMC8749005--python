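"""Exception types shared across the package."""


class NeurotrajError(Exception):
    """Base class for package errors."""


class ConfigurationError(NeurotrajError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class ParseError(NeurotrajError, ValueError):
    """Malformed input file; the message names the offending row/column."""


class ContractError(NeurotrajError, ValueError):
    """An operation precondition was violated."""
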