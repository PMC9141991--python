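"""Exception taxonomy.

Every error raised by this package derives from :class:`AnthoredoxError`
so callers can catch domain failures without masking programming errors.
"""


class AnthoredoxError(Exception):
    """Base class for all anthoredox errors."""


class ValidationError(AnthoredoxError, ValueError):
    """An input value violates a documented invariant."""


class SchemaError(ValidationError):
    """An interchange file is missing required columns/fields."""


class DuplicateKeyError(ValidationError):
    """Two records share a (compound, deprotonation_index, solvent) key."""


class ConsistencyError(AnthoredoxError):
    """Quantities that must share a frame (solvent, units) do not."""


class GeometryError(AnthoredoxError):
    """Degenerate geometry, e.g. collinear points in a torsion."""


class ConfigurationError(AnthoredoxError):
    """A required configuration constant was not supplied."""


class BracketingError(AnthoredoxError):
    """Dose-response data do not bracket the half-maximal response."""
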