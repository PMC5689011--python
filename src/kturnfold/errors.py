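"""Exception hierarchy shared across the package."""


class KTurnFoldError(Exception):
    """Base class for all package errors."""


class NoKTurnFound(KTurnFoldError):
    """No registration with a G•A/A•G core and a 3-nt bulge exists."""


class AmbiguousKTurn(KTurnFoldError):
    """More than one registration survives tie-breaking."""


class UnknownLabel(KTurnFoldError, KeyError):
    """A position label outside the annotation's vocabulary."""


class GridMismatch(KTurnFoldError, ValueError):
    """Spectra do not share a wavelength grid."""


class DegenerateAcceptor(KTurnFoldError, ValueError):
    """Acceptor-excited spectrum has no acceptor component to normalize by."""


class DomainError(KTurnFoldError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class InsufficientPoints(KTurnFoldError, ValueError):
    """Too few titration points to fit the two-state model."""


class FitDiverged(KTurnFoldError, RuntimeError):
    """Nonlinear regression failed to converge."""


class RankDeficient(KTurnFoldError, ValueError):
    """Element effects are not identifiable from the panel design."""


class EmptySet(KTurnFoldError, ValueError):
    """An aligned sequence set with no members."""
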