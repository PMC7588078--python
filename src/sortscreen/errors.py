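"""Exception hierarchy shared across the package."""


class ScreenError(Exception):
    """Base class for all sortscreen errors."""


class FormatError(ScreenError):
    """A file or table violates the expected on-disk format."""


class ValidationError(ScreenError):
    """Inputs are well-formed but mutually inconsistent."""


class ConfigurationError(ScreenError):
    """A parameter or combination of parameters is invalid."""


class NoPassingGenesError(ScreenError):
    """An FDR was requested at a threshold no real gene attains."""
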