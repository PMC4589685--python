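"""Exception hierarchy shared across the pipeline stages."""


class EcmkitError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(EcmkitError, ValueError):
    """A generator or filter parameter is outside its valid domain."""


class InvalidInputError(EcmkitError, ValueError):
    """An input array or table violates a stage precondition."""


class FormatError(EcmkitError, ValueError):
    """A file on disk is not in the expected format."""


class SchemaError(EcmkitError, ValueError):
    """A CSV table is missing required columns or contains bad rows."""


class ConfigError(EcmkitError, ValueError):
    """A configuration mapping contains unknown or invalid keys."""


class DegenerateScaleError(EcmkitError, ValueError):
    """Min-max normalization of a constant column is undefined."""


class UndefinedAlignmentError(EcmkitError, ValueError):
    """Alignment index is undefined when the angular power is all zero."""
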