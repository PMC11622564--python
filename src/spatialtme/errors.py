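"""Exception hierarchy shared by all stages."""


class SpatialTMEError(Exception):
    """Base class for all package errors."""


class SchemaError(SpatialTMEError, ValueError):
    """An input table is missing required columns or has malformed fields."""


class IntegrityError(SpatialTMEError, ValueError):
    """Input content violates a data invariant (duplicates, misalignment, negatives)."""


class ParseError(SpatialTMEError, ValueError):
    """A text format could not be parsed; carries file/line context in the message."""


class ConfigError(SpatialTMEError, ValueError):
    """A configuration value is invalid or inconsistent."""
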