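"""Exception hierarchy.

Every error raised by octdme derives from :class:`OctdmeError`, so callers
(notably the CLI) can separate domain failures from programming errors.
"""


class OctdmeError(Exception):
    """Base class for all octdme errors."""


class FormatError(OctdmeError):
    """An input file exists but is not in an accepted raster format."""


class ContractError(OctdmeError, ValueError):
    """A call violated an API precondition (shape mismatch, bad parameter)."""


class ConfigError(OctdmeError):
    """A run configuration contains an unknown key or an invalid value."""


class DegenerateClusteringError(OctdmeError):
    """The image has fewer distinct intensities than requested clusters."""


class EmptyROIError(OctdmeError):
    """Stage 1 produced (or was handed) an empty retinal mask."""


class EmptyRegionError(OctdmeError):
    """The evolving contour's interior or exterior became empty.

    Carries an optional ``iteration`` attribute when raised from inside the
    evolution loop (number of completed iterations at failure).
    """

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class NumericBlowupError(OctdmeError, FloatingPointError):
    """Non-finite values appeared during level-set evolution."""


class UndefinedMetricError(OctdmeError):
    """A metric's denominator is zero (e.g. Dice of two empty masks)."""
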