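"""Exception hierarchy.

User-facing errors derive from :class:`XtaldeconError` so the CLI can map
them to exit code 1; anything else is an internal error (exit code 2).
"""


class XtaldeconError(Exception):
    """Base class for all errors raised by xtaldecon."""


class InvalidCellError(XtaldeconError):
    """Cell lengths/angles are degenerate or outside their valid ranges."""


class UnsupportedGroupError(XtaldeconError):
    """Space-group symbol is not in the supported table."""


class InvalidRotationError(XtaldeconError):
    """Matrix is not a proper orthonormal rotation."""


class DegenerateFitError(XtaldeconError):
    """Superposition asked for with <3 points or a collinear point set."""


class InvalidResolutionError(XtaldeconError):
    """Non-positive resolution limit."""


class UndefinedCompletenessError(XtaldeconError):
    """Completeness requested against an empty reference set."""


class InvalidFactorError(XtaldeconError):
    """Supercell expansion factor below 1."""


class MisalignmentError(XtaldeconError):
    """Anchor-chain superposition rmsd above the acceptance threshold."""


class PropagationError(XtaldeconError):
    """NCS copy between chains of different length."""


class InconsistencyError(XtaldeconError):
    """Ordered supercell copies disagree beyond tolerance at collapse."""


class NoDataError(XtaldeconError):
    """Operation needs observed reflections and none are present."""


class NoOverlapError(XtaldeconError):
    """No common indices between observed and calculated sets."""


class MissingPhaseError(XtaldeconError):
    """Map coefficients requested without calculated phases."""


class UnknownElementError(XtaldeconError):
    """Element symbol with no tabulated scattering power."""


class InsufficientPairsError(XtaldeconError):
    """Too few local pairs for intensity statistics."""


class InvalidTwinOpError(XtaldeconError):
    """Twin operator is not an involution on the reflection set."""


class IncompleteCoverageError(XtaldeconError):
    """Twin operator maps reflections outside the available set."""


class InsufficientSamplingError(XtaldeconError):
    """Empirical disorder averaging with fewer than 2 realizations."""


class FormatError(XtaldeconError):
    """Malformed input file."""
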