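"""Exception hierarchy for sasbead.

All user-facing errors derive from :class:`SasBeadError` so callers (and the
CLI) can catch one base class.  Errors that are really invalid arguments also
derive from ``ValueError`` so plain-library users get the idiomatic type.
"""


class SasBeadError(Exception):
    """Base class for all sasbead errors."""


class UnsupportedSubunitError(SasBeadError, ValueError):
    """Raised for an unknown subunit kind."""


class InvalidParameterError(SasBeadError, ValueError):
    """Raised when a physical parameter is outside its valid range."""


class EmptyModelError(SasBeadError, ValueError):
    """Raised when overlap exclusion deletes every point of a model."""


class InsufficientPointsError(SasBeadError, ValueError):
    """Raised when a point cloud has fewer than two points."""


class ZeroForwardScatteringError(SasBeadError, ValueError):
    """Raised when the net excess scattering length is zero.

    A contrast-matched particle has I(0) = 0, so the normalized form factor
    P(q) = I(q)/I(0) is undefined.
    """


class GridError(SasBeadError, ValueError):
    """Raised for invalid or mismatched q grids."""


class FitFailureError(SasBeadError, RuntimeError):
    """Raised when the least-squares fit fails to converge."""


class PDBExportError(SasBeadError, ValueError):
    """Raised when a point model cannot be written as fixed-column PDB."""
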