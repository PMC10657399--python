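"""Exception types shared across the package."""


class Her2LowError(Exception):
    """Base class for package errors."""


class ConfigError(Her2LowError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class SchemaError(Her2LowError, ValueError):
    """An input table is missing a required column or has malformed rows."""


class ConsistencyError(Her2LowError, ValueError):
    """Two tables that must agree (e.g. on sample IDs) do not."""


class DegenerateInputError(Her2LowError, ValueError):
    """A statistical routine received input with no information (e.g. all-zero table)."""
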