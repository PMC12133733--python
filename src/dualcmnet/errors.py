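"""Shared exception types."""


class ValidationError(ValueError):
    """An argument value violates an operation's contract."""


class ConfigurationError(ValueError):
    """A configuration object is internally inconsistent or incomplete."""


class PlacementError(RuntimeError):
    """Kernels could not be placed on the scene canvas without overlap."""


class PairingError(ValueError):
    """Image/spectrum pairing is impossible for some class."""


class UnsupportedLayerError(TypeError):
    """A module with parameters that the MAC counter does not know."""
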