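"""Exception hierarchy shared by all pipeline stages."""


class ArtRoiError(Exception):
    """Base class for all package errors."""


class FormatError(ArtRoiError):
    """A file could not be parsed as the expected format."""


class GeometryError(ArtRoiError):
    """Inconsistent or degenerate image geometry (affines, grids, fields)."""


class DirectionError(ArtRoiError):
    """A displacement field was supplied with the wrong direction tag."""


class RegistrationError(ArtRoiError):
    """Image registration failed to converge or had no overlap to work with."""


class EventError(ArtRoiError):
    """No first-pass perfusion event could be detected in the signal."""


class PhantomSpecError(ArtRoiError):
    """A phantom specification is internally inconsistent or infeasible."""


class UndefinedStatisticError(ArtRoiError):
    """A statistic is undefined for the given input (e.g. two empty masks)."""


class ValidationError(ArtRoiError):
    """A study report failed an internal consistency check."""
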