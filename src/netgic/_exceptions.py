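"""Exception hierarchy shared across the package."""


class NetgicError(Exception):
    """Base class for all netgic-specific errors."""


class InvalidBandwidthError(NetgicError):
    """Kernel bandwidth is non-positive or non-finite."""


class DegenerateWeightingError(NetgicError):
    """Too few samples retain non-negligible kernel weight for a local fit."""


class DegenerateFitError(NetgicError):
    """A fit leaves no residual degrees of freedom or zero residual variance."""


class ConvergenceError(NetgicError):
    """An iterative solver failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class UndefinedCriterionError(NetgicError):
    """A model-selection criterion is undefined for the given fit size."""


class SelectionError(NetgicError):
    """Every point of a hyperparameter grid failed to produce a valid fit."""
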