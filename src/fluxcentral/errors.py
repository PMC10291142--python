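"""Exception hierarchy shared across the package."""


class FluxCentralError(Exception):
    """Base class for all package errors."""


class NetworkFormatError(FluxCentralError):
    """A network file could not be parsed or references unknown ids."""


class NetworkValidationError(FluxCentralError):
    """A factor graph violates a structural invariant."""


class GenerationError(FluxCentralError):
    """The synthetic generator cannot produce balanced fluxes for a graph."""


class ParameterError(FluxCentralError):
    """An argument is outside its admissible range."""


class DimensionError(FluxCentralError):
    """Mismatched shapes or misaligned ids between inputs."""


class InputError(FluxCentralError):
    """Input data is unusable (e.g., no overlap between data and network genes)."""


class TrainingError(FluxCentralError):
    """Optimization failed (e.g., non-finite loss)."""


class AlignmentError(FluxCentralError):
    """Tables that must share an index/columns do not."""


class ConfigError(FluxCentralError):
    """A run configuration failed validation; carries the full error list."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in self.errors))
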