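"""Exception types shared across the package."""


class AnchortrackError(Exception):
    """Base class for package errors."""


class InvalidInputError(AnchortrackError, ValueError):
    """An argument violates a documented precondition."""


class InvalidGeometryError(AnchortrackError, ValueError):
    """A chip layout or cell placement is geometrically impossible."""


class InsufficientSampleError(InvalidInputError):
    """Too few observations for the requested statistic."""


class DegenerateDistributionError(InvalidInputError):
    """A sample has zero spread where spread is required."""


class FormatError(AnchortrackError, ValueError):
    """A file did not round-trip or carries malformed metadata."""
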