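"""Supercell expansion and collapse for sparse-layer disordered crystals.

A crystal whose "sparse" layer molecules occupy one of n lattice-translated
slots in random order diffracts coherently only as the average structure.
The expansion trick models that average in an n-fold supercell: the ordered
molecule is replicated n times along the disorder axis, the sparse-layer
molecule appears once per supercell, and all observed reflections map onto
the sublattice (n·h, k, l) where any atom modelled in the n translated
positions contributes identically. Collapsing the supercell model back into
the small cell assigns occupancy 1 to the ordered chain and 1/n to each
sparse chain, giving fractional occupancy-weighted contents such as
1 + 1/3 ≈ 1.33 molecules per asymmetric unit for n = 3.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np

from .cell import UnitCell
from .errors import (
    InconsistencyError,
    InvalidFactorError,
    MisalignmentError,
    NoDataError,
    PropagationError,
    XtaldeconError,
)
from .geometry import superpose
from .model import StructureModel
from .reflections import ReflectionSet
from .scatter import fcalc, scale_and_rfactor

__all__ = [
    "SupercellMapping",
    "ChainRole",
    "make_mapping",
    "expand_model",
    "propagate_ncs",
    "collapse_model",
    "molecules_per_asu",
    "estimate_sparse_occupancy",
]

_AXIS_INDEX = {"a": 0, "b": 1, "c": 2}


@dataclass(frozen=True)
class SupercellMapping:
    """Link between a small cell and its n-fold expansion along one axis."""

    axis: str
    factor: int
    small_cell: UnitCell
    expanded_cell: UnitCell

    @property
    def axis_index(self) -> int:
        return _AXIS_INDEX[self.axis]

    @property
    def copy_translations(self) -> np.ndarray:
        """The n fractional translations k/n along the axis (expanded frame)."""
        t = np.zeros((self.factor, 3))
        t[:, self.axis_index] = np.arange(self.factor) / self.factor
        return t


@dataclass(frozen=True)
class ChainRole:
    """Role of one chain at collapse: 'ordered' (occ 1) or 'sparse' (occ 1/n)."""

    chain_id: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ("ordered", "sparse"):
            raise XtaldeconError(f"role must be 'ordered' or 'sparse', got {self.role!r}")


def make_mapping(cell: UnitCell, axis: str, n: int) -> SupercellMapping:
    """Mapping from ``cell`` to the cell with ``axis`` multiplied by ``n``."""
    if axis not in _AXIS_INDEX:
        raise XtaldeconError(f"axis must be one of a/b/c, got {axis!r}")
    if int(n) < 1 or n != int(n):
        raise InvalidFactorError(f"expansion factor must be an integer >= 1, got {n}")
    return SupercellMapping(
        axis=axis,
        factor=int(n),
        small_cell=cell,
        expanded_cell=cell.with_axis_scaled(axis, int(n)),
    )


def _to_expanded_frac(frac: np.ndarray, mapping: SupercellMapping) -> np.ndarray:
    """Small-cell fractional → expanded-cell fractional (same Cartesian point)."""
    out = np.array(frac, dtype=float)
    out[..., mapping.axis_index] /= mapping.factor
    return out


def _chain_letters(start: int, count: int) -> list:
    letters = string.ascii_uppercase
    return [letters[(start + i) % len(letters)] * (1 + (start + i) // len(letters)) for i in range(count)]


def expand_model(
    ordered_model: StructureModel,
    alt_model: StructureModel | None,
    mapping: SupercellMapping,
    anchor_chain: str = "A",
    sparse_chains: tuple = (),
    rmsd_threshold: float = 5.0,
) -> StructureModel:
    """Build the n-fold supercell model: n ordered copies plus sparse chains.

    The anchor chain of ``ordered_model`` is replicated ``n`` times, copy k
    translated by k/n along the mapping axis (expanded-cell fractions).
    Sparse chains are taken from ``alt_model`` (or from ``ordered_model``
    itself when ``alt_model`` is None) after superposing its anchor chain
    onto the ordered model's anchor; an anchor rmsd above ``rmsd_threshold``
    Å aborts the transfer. Chains are renamed A, B, C, … — ordered copies
    first, sparse chains continuing alphabetically.
    """
    if anchor_chain not in ordered_model.chains:
        raise XtaldeconError(f"anchor chain {anchor_chain!r} missing from ordered model")
    n = mapping.factor
    # a centring translation with a component v along the expansion axis is a
    # symmetry of both cells only when v·(n − 1) is integral (C-centring on
    # the expanded axis needs odd n); otherwise the expanded group is wrong
    for vec in ordered_model.spacegroup.centring_vectors():
        v = vec[mapping.axis_index]
        if v != 0 and abs(v * (n - 1) - round(v * (n - 1))) > 1e-9:
            raise XtaldeconError(
                f"expansion factor {n} along {mapping.axis} is incompatible with the "
                f"{ordered_model.spacegroup.symbol} centring translation {tuple(vec)}"
            )
    anchor_sites = ordered_model.chains[anchor_chain]
    anchor_frac = np.array([s.position for s in anchor_sites])
    chains: dict = {}
    names = _chain_letters(0, n + len(sparse_chains))
    base = _to_expanded_frac(anchor_frac, mapping)
    for k in range(n):
        shift = mapping.copy_translations[k]
        cid = names[k]
        chains[cid] = [
            replace(s, chain_id=cid, position=tuple(base[i] + shift))
            for i, s in enumerate(anchor_sites)
        ]
    if sparse_chains:
        source = alt_model if alt_model is not None else ordered_model
        for cid in sparse_chains:
            if cid not in source.chains:
                raise XtaldeconError(f"sparse chain {cid!r} missing from source model")
        if alt_model is not None:
            if anchor_chain not in alt_model.chains:
                raise XtaldeconError(f"anchor chain {anchor_chain!r} missing from alt model")
            fit = superpose(
                alt_model.cartesian_positions(anchor_chain),
                ordered_model.cartesian_positions(anchor_chain),
            )
            if fit.rmsd > rmsd_threshold:
                raise MisalignmentError(
                    f"anchor superposition rmsd {fit.rmsd:.2f} Å exceeds {rmsd_threshold} Å"
                )
            transform = fit.transform
        else:
            transform = lambda c: c  # noqa: E731 - identity transfer
        for j, cid in enumerate(sparse_chains):
            cart = transform(source.cell.orthogonalize(source.positions(cid)))
            frac_small = ordered_model.cell.fractionalize(cart)
            frac_exp = _to_expanded_frac(frac_small, mapping)
            new_id = names[n + j]
            chains[new_id] = [
                replace(s, chain_id=new_id, position=tuple(frac_exp[i]))
                for i, s in enumerate(source.chains[cid])
            ]
    return StructureModel(mapping.expanded_cell, ordered_model.spacegroup, chains)


def _copy_offset(source: np.ndarray, target: np.ndarray, mapping: SupercellMapping) -> float:
    """Translation (multiple of 1/n along the axis) taking source to target."""
    delta = float(np.mean(target[:, mapping.axis_index] - source[:, mapping.axis_index]))
    return round(delta * mapping.factor) / mapping.factor


def propagate_ncs(
    expanded: StructureModel,
    source_chain: str,
    target_chains: tuple,
    mapping: SupercellMapping,
) -> StructureModel:
    """Copy the source chain onto each target chain, lattice translation apart.

    After propagation every target is an exact translated image of the
    source (the supercell analogue of strict NCS between the ordered
    copies); chains outside ``target_chains`` are untouched. Idempotent.
    """
    out = expanded.copy()
    src_sites = out.chains[source_chain]
    src = np.array([s.position for s in src_sites])
    for cid in target_chains:
        tgt_sites = out.chains[cid]
        if len(tgt_sites) != len(src_sites):
            raise PropagationError(
                f"chain {cid} has {len(tgt_sites)} atoms, source {source_chain} has {len(src_sites)}"
            )
        shift = _copy_offset(src, np.array([s.position for s in tgt_sites]), mapping)
        vec = np.zeros(3)
        vec[mapping.axis_index] = shift
        out.chains[cid] = [
            replace(s, chain_id=cid, position=tuple(src[i] + vec)) for i, s in enumerate(src_sites)
        ]
    return out


def collapse_model(
    expanded: StructureModel,
    mapping: SupercellMapping,
    roles: tuple,
    tolerance: float = 1e-6,
) -> StructureModel:
    """Fold a supercell model back into the small cell with 1/n occupancies.

    The ordered copies must agree (after removing their k/n translations)
    to ``tolerance`` in fractional units; copy 0 (smallest translation) is
    kept at occupancy 1. Each sparse chain is kept at occupancy 1/n.
    Coordinates refold into [0, 1) of the small cell.
    """
    n = mapping.factor
    ordered = [r.chain_id for r in roles if r.role == "ordered"]
    sparse = [r.chain_id for r in roles if r.role == "sparse"]
    if not ordered:
        raise XtaldeconError("at least one ordered chain is required")
    if len(ordered) % n != 0:
        raise InconsistencyError(
            f"{len(ordered)} ordered chains cannot form groups of {n} supercell copies"
        )
    ax = mapping.axis_index

    def refold(frac: np.ndarray) -> np.ndarray:
        out = np.array(frac, dtype=float)
        out[:, ax] = np.mod(out[:, ax] * n, 1.0)
        return out

    chains: dict = {}
    for g in range(len(ordered) // n):
        group = ordered[g * n : (g + 1) * n]
        ref = np.array([s.position for s in expanded.chains[group[0]]])
        offsets = []
        for cid in group:
            pos = np.array([s.position for s in expanded.chains[cid]])
            if pos.shape != ref.shape:
                raise InconsistencyError(f"ordered copies {group[0]}/{cid} differ in length")
            shift = _copy_offset(ref, pos, mapping)
            dev = pos.copy()
            dev[:, ax] -= shift
            if np.max(np.abs(dev - ref)) > tolerance:
                raise InconsistencyError(
                    f"ordered copies {group[0]} and {cid} deviate beyond tolerance after "
                    "removing the lattice translation; propagate NCS before collapsing"
                )
            offsets.append(shift)
        keep = group[int(np.argmin(offsets))]
        pos = refold(np.array([s.position for s in expanded.chains[keep]]))
        chains[keep] = [
            replace(s, occupancy=1.0, position=tuple(pos[i]))
            for i, s in enumerate(expanded.chains[keep])
        ]
    for cid in sparse:
        pos = refold(np.array([s.position for s in expanded.chains[cid]]))
        chains[cid] = [
            replace(s, occupancy=1.0 / n, position=tuple(pos[i]))
            for i, s in enumerate(expanded.chains[cid])
        ]
    return StructureModel(mapping.small_cell, expanded.spacegroup, chains)


def molecules_per_asu(model: StructureModel) -> float:
    """Occupancy-weighted number of chains in the asymmetric unit."""
    return float(sum(np.mean([s.occupancy for s in sites]) for sites in model.chains.values()))


def estimate_sparse_occupancy(
    small_model: StructureModel,
    sparse_chain: str,
    refls: ReflectionSet,
    grid: np.ndarray | None = None,
):
    """Grid-scan the sparse-chain occupancy against observed amplitudes.

    For each occupancy on the grid the structure factors are recomputed and
    the scaled R factor against ``refls`` measured; returns the minimizing
    occupancy (ties broken toward the smaller value) and the full
    (occupancy, R) profile.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    obs = refls.data["observed"].to_numpy(bool)
    if not obs.any():
        raise NoDataError("occupancy scan needs observed reflections")
    profile = []
    for occ in np.asarray(grid, dtype=float):
        trial = small_model.with_chain_occupancy(sparse_chain, float(occ))
        calc = fcalc(trial, refls)
        profile.append((float(occ), scale_and_rfactor(refls, calc).r_factor))
    rs = np.array([r for _, r in profile])
    best = float(profile[int(np.argmin(rs))][0])  # argmin returns first (smallest occ) on ties
    return best, profile
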