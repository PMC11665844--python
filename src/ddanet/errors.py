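"""Exception hierarchy shared across the package."""


class DDANetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DDANetError, ValueError):
    """A configuration value is invalid or inconsistent (the message names it)."""


class DimensionError(DDANetError, ValueError):
    """An array has an inadmissible shape (the message names the offending axis)."""


class GenerationError(DDANetError, RuntimeError):
    """The phantom generator could not satisfy its configuration."""


class ImageFormatError(DDANetError, ValueError):
    """An on-disk image is not in an accepted format (e.g. not grayscale)."""
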