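"""Exception hierarchy for octvol.

All library errors derive from :class:`OctvolError` so the CLI can map
them to exit code 1 while genuine usage mistakes surface as exit code 2.
"""


class OctvolError(Exception):
    """Base class for all octvol errors."""


class SchemaError(OctvolError):
    """Input file does not match the expected schema; names the offending key/row."""


class UnitError(OctvolError):
    """Inconsistent or missing unit metadata (e.g. pixel vertices without scales)."""


class DegenerateContourError(OctvolError):
    """Contour has fewer than 3 vertices or zero extent."""


class ContourValidityError(OctvolError):
    """Contour is self-intersecting; mis-traced contours are rejected, not repaired."""


class EmptyEntityError(OctvolError):
    """Requested entity label occurs nowhere in the annotation stack."""


class ConfigurationError(OctvolError):
    """Required configuration (e.g. a fovea center for the circular protocol) is missing."""


class InsufficientDataError(OctvolError):
    """Too few paired measurements for the requested statistic."""


class FormatError(OctvolError):
    """Unknown or unwritable output format."""
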