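"""Exception hierarchy.

``DataError`` marks problems with the input data (malformed records,
unaligned sequences, undefined distances where defined ones are required);
``ConfigurationError`` marks invalid parameters or missing configuration.
"""


class CoithreshError(Exception):
    """Base class for all package errors."""


class DataError(CoithreshError, ValueError):
    """The input data violate a precondition of the requested operation."""


class ConfigurationError(CoithreshError, ValueError):
    """A parameter set or file layout is invalid or incomplete."""
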