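"""Exception taxonomy shared across the package."""


class QueueFlowError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(QueueFlowError, ValueError):
    """A configuration object or file is invalid."""


class SchemaError(QueueFlowError, ValueError):
    """An input file does not have the expected columns."""


class ParseError(QueueFlowError, ValueError):
    """A field value (typically a timestamp) could not be parsed."""


class ValidationError(QueueFlowError, ValueError):
    """A record violates a data-model invariant."""


class EmptyInputError(QueueFlowError, ValueError):
    """An operation that requires data received none."""


class DegenerateInputError(QueueFlowError, ValueError):
    """The input is formally valid but makes the computation meaningless
    (e.g. a constant regression target)."""
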