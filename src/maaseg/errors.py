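"""Exception types shared across the package."""


class MaasegError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MaasegError):
    """Invalid configuration value or schema violation."""


class DimensionError(MaasegError):
    """Image/raster dimensions incompatible with the requested operation."""


class PipelineError(MaasegError):
    """A pipeline stage cannot run (e.g. missing upstream artifact)."""


class UndefinedLossError(MaasegError):
    """A loss was requested over an empty set of samples/pixels."""
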