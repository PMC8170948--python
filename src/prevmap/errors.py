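"""Exception hierarchy used across the package."""


class PrevmapError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PrevmapError):
    """Invalid configuration (bad probabilities, counts, paths...)."""


class InputError(PrevmapError):
    """Invalid data passed to an operation (bad values, unknown codes...)."""


class SchemaError(PrevmapError):
    """Design-matrix schema inconsistent with the data it is applied to."""
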