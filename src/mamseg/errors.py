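"""Exception hierarchy shared by all pipeline stages."""


class MamsegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MamsegError, ValueError):
    """A parameter violates its documented precondition."""


class DegenerateImageError(MamsegError, ValueError):
    """The image has no usable dynamic range (e.g. spatially constant)."""


class GeometryError(MamsegError, ValueError):
    """A contour or point violates a geometric precondition."""


class SearchBandNotFoundError(MamsegError, RuntimeError):
    """No sufficiently dense chain of nested iso-level contours exists."""


class NumericalInstabilityError(MamsegError, RuntimeError):
    """An explicit time-stepping scheme produced non-finite values."""


class ContourVanishedError(MamsegError, RuntimeError):
    """The evolving level-set function lost one of its signs."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"contour vanished at iteration {iteration}")


class DegeneratePartitionError(MamsegError, ValueError):
    """A region statistic is undefined (empty region or zero denominator)."""
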