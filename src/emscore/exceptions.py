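"""Package-specific exception types."""


class EmscoreError(Exception):
    """Base class for all emscore errors."""


class ConfigurationError(EmscoreError):
    """Invalid configuration value or distribution parameter."""


class PlacementError(EmscoreError):
    """A synthetic field was too small to place the requested cells."""


class DemodulationError(EmscoreError):
    """No usable off-axis carrier peak was found in a hologram spectrum."""


class SchemaError(EmscoreError):
    """A feature table does not match the schema a model was trained on."""
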