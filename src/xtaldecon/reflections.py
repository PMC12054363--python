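"""Reflection sets: unique-index generation, reindexing, completeness, free flags.

A :class:`ReflectionSet` wraps a pandas DataFrame with one row per unique
reflection. Indices are stored reduced to a canonical asymmetric
representative: the lexicographically largest of all point-group (including
Friedel) equivalents. Columns:

``h k l`` (int), ``f_obs sigma intensity f_calc phi_calc`` (float, NaN when
absent), ``free`` (int8: −1 unassigned / 0 work / 1 free), ``observed`` (bool).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell import UnitCell
from .errors import (
    InvalidResolutionError,
    UndefinedCompletenessError,
)
from .symmetry import SpaceGroupOps, get_spacegroup

__all__ = [
    "ReflectionSet",
    "canonical_hkl",
    "generate_unique_hkl",
    "reindex_supercell",
    "completeness",
    "assign_free_flags",
]

COLUMNS = ["h", "k", "l", "f_obs", "sigma", "intensity", "f_calc", "phi_calc", "free", "observed"]


def _empty_frame(n: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "h": np.zeros(n, dtype=int),
            "k": np.zeros(n, dtype=int),
            "l": np.zeros(n, dtype=int),
            "f_obs": np.full(n, np.nan),
            "sigma": np.full(n, np.nan),
            "intensity": np.full(n, np.nan),
            "f_calc": np.full(n, np.nan),
            "phi_calc": np.full(n, np.nan),
            "free": np.full(n, -1, dtype=np.int8),
            "observed": np.zeros(n, dtype=bool),
        }
    )


@dataclass
class ReflectionSet:
    """Unique reflections of one crystal form."""

    cell: UnitCell
    spacegroup: SpaceGroupOps
    data: pd.DataFrame = field(default_factory=_empty_frame)
    d_min: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.spacegroup, str):
            self.spacegroup = get_spacegroup(self.spacegroup)
        for col in COLUMNS:
            if col not in self.data.columns:
                empty = _empty_frame(len(self.data))
                self.data[col] = empty[col]
        self.data = self.data[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def hkl(self) -> np.ndarray:
        return self.data[["h", "k", "l"]].to_numpy(dtype=int)

    @property
    def d(self) -> np.ndarray:
        """Resolution of every reflection in Å."""
        return self.cell.d_spacing(self.hkl)

    @property
    def n_observed(self) -> int:
        return int(self.data["observed"].sum())

    def intensities(self) -> np.ndarray:
        """Intensity column, falling back to |F_obs|² where absent."""
        i = self.data["intensity"].to_numpy(float).copy()
        missing = np.isnan(i)
        i[missing] = self.data["f_obs"].to_numpy(float)[missing] ** 2
        return i

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(self.cell, self.spacegroup, self.data.copy(), self.d_min)

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(self.cell, self.spacegroup, self.data[mask].copy(), self.d_min)


def canonical_hkl(hkl: np.ndarray, sg: SpaceGroupOps) -> np.ndarray:
    """Reduce indices to the lexicographically largest point-group equivalent.

    Equivalents are h → h·R over the Laue group (point-group rotations plus
    the Friedel inversion); the reduction rule is a total order, so every
    orbit has exactly one representative.
    """
    h = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
    best = None
    for rot in sg.point_group_rotations():
        cand = h @ rot
        if best is None:
            best = cand
        else:
            # lexicographic comparison on (h, k, l)
            gt = (cand[:, 0] > best[:, 0]) | (
                (cand[:, 0] == best[:, 0])
                & ((cand[:, 1] > best[:, 1]) | ((cand[:, 1] == best[:, 1]) & (cand[:, 2] > best[:, 2])))
            )
            best = np.where(gt[:, None], cand, best)
    return best.reshape(np.shape(hkl))


def generate_unique_hkl(cell: UnitCell, sg: SpaceGroupOps, d_min: float) -> ReflectionSet:
    """Every lattice-allowed unique reflection with d ≥ d_min, unobserved.

    Enumerates the full index box, keeps the resolution sphere, drops
    centring-extinguished indices and (0,0,0), and reduces to canonical
    representatives.
    """
    if d_min <= 0:
        raise InvalidResolutionError(f"d_min must be positive, got {d_min}")
    gstar = cell.reciprocal_metric_tensor
    # |h_i| = |a_i · s| <= |a_i|/d_min bounds the index box for the sphere
    g = cell.metric_tensor
    lims = [int(np.floor(np.sqrt(g[i, i]) / d_min)) for i in range(3)]
    hh, kk, ll = np.meshgrid(
        np.arange(-lims[0], lims[0] + 1),
        np.arange(-lims[1], lims[1] + 1),
        np.arange(-lims[2], lims[2] + 1),
        indexing="ij",
    )
    hkl = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()]).astype(np.int64)
    s2 = np.einsum("ni,ij,nj->n", hkl.astype(float), gstar, hkl.astype(float))
    mask = (s2 <= 1.0 / d_min**2 + 1e-12) & (s2 > 0)
    hkl = hkl[mask]
    hkl = hkl[sg.is_centring_allowed(hkl)]
    canon = canonical_hkl(hkl, sg)
    unique = np.unique(canon, axis=0)
    frame = _empty_frame(len(unique))
    frame[["h", "k", "l"]] = unique
    return ReflectionSet(cell, sg, frame, d_min=d_min)


def reindex_supercell(refls: ReflectionSet, mapping) -> ReflectionSet:
    """Re-express a reflection set in an n-fold expanded cell.

    Expansion of axis ``a`` by n maps (h, k, l) → (n·h, k, l) (cyclically
    for the other axes); the d-spacing of every reflection is unchanged
    because the real axis is scaled by the same factor. Every data column,
    including observed flags, is carried over.
    """
    axis_idx = {"a": 0, "b": 1, "c": 2}[mapping.axis]
    data = refls.data.copy()
    col = ["h", "k", "l"][axis_idx]
    data[col] = data[col] * mapping.factor
    return ReflectionSet(mapping.expanded_cell, refls.spacegroup, data, refls.d_min)


def completeness(refls: ReflectionSet, d_min: float) -> float:
    """Observed fraction of the lattice-allowed unique reflections to d_min.

    The denominator is regenerated from the set's cell and space group;
    centring-extinguished indices are excluded from both counts.
    """
    reference = generate_unique_hkl(refls.cell, refls.spacegroup, d_min)
    n_ref = len(reference)
    if n_ref == 0:
        raise UndefinedCompletenessError(f"no lattice-allowed reflections to d_min {d_min}")
    obs = refls.data["observed"].to_numpy(bool) & (refls.d >= d_min - 1e-9)
    obs_canon = canonical_hkl(refls.hkl[obs], refls.spacegroup)
    ref_keys = set(map(tuple, reference.hkl))
    n_obs = sum(tuple(row) in ref_keys for row in obs_canon)
    return n_obs / n_ref


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer (stable across runs and platforms)."""
    x = x.astype(np.uint64)
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _hkl_hash(seed: int, hkl: np.ndarray) -> np.ndarray:
    """Deterministic per-index hash in [0, 1), a pure function of (seed, h, k, l)."""
    h = hkl.astype(np.int64)
    acc = np.full(len(h), np.uint64(seed) & np.uint64(0xFFFFFFFFFFFFFFFF))
    for i in range(3):
        acc = _splitmix64(acc ^ h[:, i].astype(np.uint64))
    return acc.astype(np.float64) / 2.0**64


def assign_free_flags(
    refls: ReflectionSet,
    fraction: float = 0.05,
    seed: int = 0,
    include_unmeasured: bool = True,
) -> ReflectionSet:
    """Partition reflections into work (0) and free (1) sets.

    The flag of each reflection is a deterministic hash of (seed, h, k, l)
    compared against ``fraction``, so the flag of an index never depends on
    which other reflections are present and survives reindexing of the
    surviving indices. With ``include_unmeasured`` the full unique set to the
    set's d_min is flagged — unmeasured indices are added as unobserved rows —
    matching the practice of generating free flags for all reflections,
    measured or not.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    out = refls.copy()
    if include_unmeasured and refls.d_min is not None:
        full = generate_unique_hkl(refls.cell, refls.spacegroup, refls.d_min)
        have = set(map(tuple, canonical_hkl(out.hkl, out.spacegroup)))
        missing = np.array([row for row in full.hkl if tuple(row) not in have], dtype=int)
        if len(missing):
            extra = _empty_frame(len(missing))
            extra[["h", "k", "l"]] = missing
            out.data = pd.concat([out.data, extra], ignore_index=True)
    flags = _hkl_hash(seed, canonical_hkl(out.hkl, out.spacegroup)) < fraction
    out.data["free"] = flags.astype(np.int8)
    return out
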