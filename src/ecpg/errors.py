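"""Exception hierarchy for the ecpg package."""


class EcpgError(Exception):
    """Base class for all ecpg errors."""


class FormatError(EcpgError):
    """An input file violates the expected CSV/BED format."""


class AlignmentError(EcpgError):
    """Samples cannot be aligned across the three input matrices."""


class ModelError(EcpgError):
    """The regression design is unusable (rank deficiency, too few samples)."""


class ConfigurationError(EcpgError):
    """A run configuration value is invalid or unsatisfiable."""


class DeviceError(EcpgError):
    """A requested compute device is not available."""
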