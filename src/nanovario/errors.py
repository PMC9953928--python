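"""Exception hierarchy used across the package."""


class NanovarioError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NanovarioError, ValueError):
    """An argument or spec field is out of its valid domain."""


class RasterFormatError(NanovarioError, ValueError):
    """A raster file is malformed (non-square, non-finite entries, ...)."""


class MetadataError(NanovarioError, ValueError):
    """Required physical metadata (scan size, channel) is missing."""


class DegenerateSurfaceError(NanovarioError, ValueError):
    """An estimator cannot run on this surface (e.g. constant field)."""
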