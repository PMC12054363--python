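"""Unit-cell arithmetic.

A :class:`UnitCell` stores the six cell parameters and provides the metric
tensor, volume, and the fractional/orthogonal coordinate transforms in the
standard PDB orthogonalization convention (``a`` along ``x``, ``b`` in the
``x``–``y`` plane).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidCellError

__all__ = ["UnitCell", "cell_volume"]


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell.

    Parameters
    ----------
    a, b, c
        Cell edge lengths in Å, all positive.
    alpha, beta, gamma
        Cell angles in degrees, each in the open interval (0, 180); the
        combination must give a positive cell volume.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    _orth: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angles must lie in (0, 180): {self}")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0.0:
            raise InvalidCellError(f"degenerate angle combination: {self}")
        v = self.a * self.b * self.c * math.sqrt(arg)
        # PDB convention: a along x, b in the x-y plane.
        orth = np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (self.a * self.b * sg)],
            ]
        )
        object.__setattr__(self, "_orth", orth)
        object.__setattr__(self, "_volume", v)

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (closed-form metric expression)."""
        return self._volume  # type: ignore[attr-defined]

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3×3 matrix M with x_cart = M @ x_frac."""
        return self._orth.copy()

    @property
    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self._orth)

    @property
    def metric_tensor(self) -> np.ndarray:
        """Real-space metric G; |v_frac|² = v G vᵀ."""
        return self._orth.T @ self._orth

    @property
    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal metric G*; s² = 1/d² = h G* hᵀ for integer h."""
        return np.linalg.inv(self.metric_tensor)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional → Cartesian Å. Accepts (..., 3) arrays."""
        return np.asarray(frac, dtype=float) @ self._orth.T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        """Cartesian Å → fractional."""
        return np.asarray(cart, dtype=float) @ self.fractionalization_matrix.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d in Å for Miller indices ``hkl`` of shape (..., 3)."""
        h = np.asarray(hkl, dtype=float)
        s2 = np.einsum("...i,ij,...j->...", h, self.reciprocal_metric_tensor, h)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(s2)

    def with_axis_scaled(self, axis: str, factor: float) -> "UnitCell":
        """Copy of the cell with one axis length multiplied by ``factor``."""
        lengths = {"a": self.a, "b": self.b, "c": self.c}
        if axis not in lengths:
            raise InvalidCellError(f"axis must be one of a/b/c, got {axis!r}")
        lengths[axis] *= factor
        return UnitCell(lengths["a"], lengths["b"], lengths["c"], self.alpha, self.beta, self.gamma)


def cell_volume(cell: UnitCell) -> float:
    """Volume of ``cell`` in Å³."""
    return cell.volume
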