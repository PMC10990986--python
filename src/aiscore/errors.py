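"""Exception types shared across the package."""


class FormatError(ValueError):
    """An input file does not have the expected layout (e.g., a missing column)."""


class ValidationError(ValueError):
    """Input content violates a contract (duplicate ids, bad category labels, ...)."""


class ConsistencyError(ValidationError):
    """Provided narrative totals disagree with totals recomputed from segments."""


class ConfigError(ValueError):
    """A configuration value is invalid or refers to an unknown component."""


class DataError(ValueError):
    """The data cannot support the requested operation (e.g., an empty class)."""
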