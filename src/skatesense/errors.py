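"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: config errors -> 2, data errors -> 3,
numerical failures -> 4.
"""


class SkatesenseError(Exception):
    """Base class for all package errors."""


class ConfigError(SkatesenseError):
    """Invalid configuration or CLI arguments."""


class SchemaError(SkatesenseError):
    """Input table violates the expected schema (missing/unparseable columns)."""


class DataError(SkatesenseError):
    """Data are structurally valid but unusable (empty, degenerate range...)."""


class NumericalError(SkatesenseError):
    """Training or prediction produced non-finite values."""
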