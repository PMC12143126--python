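"""Exception hierarchy for thetaflow.

Every error raised on purpose by the package derives from
:class:`ThetaflowError`, so callers can catch the package's own failures
without swallowing programming errors.
"""


class ThetaflowError(Exception):
    """Base class for all thetaflow errors."""


class ConfigurationError(ThetaflowError, ValueError):
    """Invalid parameter combination (durations, accuracies, bands, ...)."""


class StabilityError(ThetaflowError, ValueError):
    """A simulated autoregressive system would be non-stationary."""


class GeometryError(ThetaflowError, ValueError):
    """Degenerate sensor/voxel geometry (coincident sensors etc.)."""


class FormatError(ThetaflowError, IOError):
    """A file on disk violates the expected on-disk format."""


class ResolutionError(ThetaflowError, ValueError):
    """A spectral estimate was requested below what the data can resolve."""


class EmptySelectionError(ThetaflowError, ValueError):
    """A selection (events, epochs, voxels) matched nothing."""


class PairingError(ThetaflowError, ValueError):
    """Paired statistics received inputs that are not aligned by subject."""


class NumericalError(ThetaflowError, ArithmeticError):
    """A numerical routine failed (singular matrix, divergent fit, ...)."""


class IncompleteROIError(ThetaflowError, ValueError):
    """ROI construction could not populate every required region."""


class CompletenessError(ThetaflowError, ValueError):
    """A report is missing required cells."""
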