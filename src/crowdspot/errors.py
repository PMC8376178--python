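"""Exception types shared across the toolkit."""


class CrowdspotError(Exception):
    """Base class for all package-specific errors."""


class PackingError(CrowdspotError):
    """Requested spot layout cannot be placed under the spacing constraint."""


class BoundaryError(CrowdspotError):
    """A coordinate or measurement window falls outside the image."""


class SchemaError(CrowdspotError):
    """An annotation table is missing required columns."""


class InsufficientAnnotationsError(CrowdspotError):
    """Too few ground-truth points for parameter extraction."""


class ConfigError(CrowdspotError):
    """Invalid or unknown pipeline configuration."""
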