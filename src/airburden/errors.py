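"""Exception hierarchy used across the package."""


class AirburdenError(Exception):
    """Base class for all package errors."""


class FormatError(AirburdenError):
    """A file does not conform to the expected on-disk format."""


class GeometryError(AirburdenError):
    """An invalid region geometry was supplied."""


class BoundsError(AirburdenError):
    """A point lies outside the grid bounding box."""


class InputError(AirburdenError):
    """An in-memory input violates an operation precondition."""


class ConfigError(AirburdenError):
    """A configuration value is inconsistent or missing."""
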