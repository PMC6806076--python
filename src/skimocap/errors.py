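"""Exception hierarchy.

Distinct classes map to distinct CLI exit codes: configuration problems,
data/schema problems, and computation (geometry/numerics) problems.
"""


class SkimocapError(Exception):
    """Base class for all package errors."""


class ConfigError(SkimocapError):
    """Invalid parameter or configuration value."""


class DataError(SkimocapError):
    """Malformed, missing or inconsistent input data."""


class SchemaError(DataError):
    """Input violates the documented file schema."""


class MissingDataError(DataError):
    """A required keypoint is invalid in a frame."""


class DegenerateGeometryError(SkimocapError):
    """A geometric construction is undefined (zero-length vector, parallel axes...)."""
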