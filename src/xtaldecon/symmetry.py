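"""Space-group operations for the groups the toolkit needs.

Operation tables are hard-coded for P1, P2₁ (unique b), C222₁ and P6₃ —
the groups occurring in the crystal forms this package targets. Rotation
parts act on fractional coordinates (and, transposed, on Miller indices);
translations are in fractions of the cell edges. Adding further groups
means adding a table entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import UnsupportedGroupError

__all__ = ["SymOp", "SpaceGroupOps", "get_spacegroup", "SUPPORTED_SYMBOLS"]


@dataclass(frozen=True)
class SymOp:
    """One symmetry operation x → R x + t in fractional coordinates."""

    rot: tuple  # 3×3 nested tuple of ints
    tran: tuple  # 3 Fractions

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=int)

    @property
    def tran_array(self) -> np.ndarray:
        return np.array([float(t) for t in self.tran])

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.rot_array.T + self.tran_array


def _op(rot, tran=(0, 0, 0)) -> SymOp:
    return SymOp(tuple(tuple(r) for r in rot), tuple(Fraction(t) for t in tran))


_I = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
_H = Fraction(1, 2)

# International Tables general-position operators.
_TABLES = {
    "P1": {
        "number": 1,
        "hm": "P 1",
        "ops": [_op(_I)],
        "centring": [(0, 0, 0)],
    },
    "P21": {
        "number": 4,
        "hm": "P 1 21 1",
        "ops": [
            _op(_I),
            _op(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0, _H, 0)),
        ],
        "centring": [(0, 0, 0)],
    },
    "C2221": {
        "number": 20,
        "hm": "C 2 2 21",
        "ops": [
            _op(_I),
            _op(((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0, 0, _H)),
            _op(((1, 0, 0), (0, -1, 0), (0, 0, -1))),
            _op(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0, 0, _H)),
        ],
        "centring": [(0, 0, 0), (_H, _H, 0)],
    },
    "P63": {
        "number": 173,
        "hm": "P 63",
        "ops": [
            _op(_I),
            _op(((1, -1, 0), (1, 0, 0), (0, 0, 1)), (0, 0, _H)),
            _op(((0, -1, 0), (1, -1, 0), (0, 0, 1))),
            _op(((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0, 0, _H)),
            _op(((-1, 1, 0), (-1, 0, 0), (0, 0, 1))),
            _op(((0, 1, 0), (-1, 1, 0), (0, 0, 1)), (0, 0, _H)),
        ],
        "centring": [(0, 0, 0)],
    },
}

SUPPORTED_SYMBOLS = tuple(_TABLES)

_ALIASES = {
    "P 1": "P1",
    "P 1 21 1": "P21",
    "P 21": "P21",
    "P121 1": "P21",
    "P 21 ": "P21",
    "C 2 2 21": "C2221",
    "P 63": "P63",
}


@dataclass(frozen=True)
class SpaceGroupOps:
    """Closed set of symmetry operations of one space group.

    ``operations`` are the general-position operators; ``centring`` holds the
    lattice-centring translations (identity included), so the full operator
    list is every operation combined with every centring vector.
    """

    symbol: str
    number: int
    hm: str
    operations: tuple
    centring: tuple

    @property
    def n_ops(self) -> int:
        return len(self.operations)

    @property
    def n_centring(self) -> int:
        return len(self.centring)

    @property
    def multiplicity(self) -> int:
        """General-position multiplicity Z (ops × centring vectors)."""
        return self.n_ops * self.n_centring

    def centring_vectors(self) -> np.ndarray:
        return np.array([[float(Fraction(x)) for x in v] for v in self.centring])

    def rotations(self) -> np.ndarray:
        """(n_ops, 3, 3) integer rotation parts."""
        return np.stack([op.rot_array for op in self.operations])

    def translations(self) -> np.ndarray:
        return np.stack([op.tran_array for op in self.operations])

    def point_group_rotations(self) -> np.ndarray:
        """Unique rotation parts including the Friedel inversion (Laue group)."""
        rots = {tuple(map(tuple, op.rot_array)) for op in self.operations}
        rots |= {tuple(map(tuple, -op.rot_array)) for op in self.operations}
        return np.stack([np.array(r, dtype=int) for r in sorted(rots)])

    def is_centring_allowed(self, hkl: np.ndarray) -> np.ndarray:
        """Boolean mask of reflections not extinguished by lattice centring.

        A reflection survives iff exp(2πi h·v) = 1 for every centring
        vector v (C-centring: h + k even).
        """
        h = np.asarray(hkl, dtype=int)
        mask = np.ones(h.shape[:-1], dtype=bool)
        for vec in self.centring:
            num = [Fraction(x) for x in vec]
            if all(x == 0 for x in num):
                continue
            s = sum(h[..., i] * float(num[i]) for i in range(3))
            mask &= np.isclose(np.mod(s, 1.0), 0.0)
        return mask


def get_spacegroup(symbol: str) -> SpaceGroupOps:
    """Look up a supported space group by symbol (``P1``, ``P21``, ``C2221``, ``P63``).

    Hermann–Mauguin spellings with spaces (e.g. ``C 2 2 21``) are accepted.
    """
    key = symbol.strip()
    key = _ALIASES.get(key, key.replace(" ", "").upper())
    key = {"P1211": "P21"}.get(key, key)
    if key not in _TABLES:
        raise UnsupportedGroupError(
            f"space group {symbol!r} not supported (supported: {', '.join(SUPPORTED_SYMBOLS)})"
        )
    t = _TABLES[key]
    return SpaceGroupOps(
        symbol=key,
        number=t["number"],
        hm=t["hm"],
        operations=tuple(t["ops"]),
        centring=tuple(t["centring"]),
    )
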