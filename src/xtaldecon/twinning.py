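"""Twinning and pseudo-symmetry diagnostics.

The L-test compares unrelated local pairs of intensities,
L = (I₁ − I₂)/(I₁ + I₂): for untwinned acentric data L is uniform on
(−1, 1), giving ⟨|L|⟩ = 1/2 and ⟨L²⟩ = 1/3; a perfect merohedral twin gives
3/8 and 1/5. The H-test compares twin-law-related mates,
H = |I(h) − I(Th)|/(I(h) + I(Th)); for a two-individual twin of fraction α,
⟨H⟩ = (1 − 2α)·⟨|L|⟩ = (1 − 2α)/2, so α̂ = 1/2 − ⟨H⟩.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientPairsError, InvalidTwinOpError, XtaldeconError
from .geometry import superpose
from .model import StructureModel
from .reflections import ReflectionSet, canonical_hkl

__all__ = ["TwinStats", "l_test", "h_test", "symmetrized_rmsd"]

#: Reference moments of the L statistic (untwinned / perfect twin, acentric).
UNTWINNED_MEAN_ABS_L = 0.5
UNTWINNED_MEAN_L2 = 1.0 / 3.0
PERFECT_TWIN_MEAN_ABS_L = 0.375
PERFECT_TWIN_MEAN_L2 = 0.2


@dataclass(frozen=True)
class TwinStats:
    """Moments of the pairwise intensity statistic and pair count."""

    mean_abs_L: float
    mean_L2: float
    n_pairs: int
    alpha_hat: float | None = None  # twin-fraction estimate (H-test only)


def _intensity_lookup(refls: ReflectionSet):
    intens = refls.intensities()
    if np.isnan(intens).any():
        raise XtaldeconError("intensities (or f_obs) required for twin statistics")
    canon = canonical_hkl(refls.hkl, refls.spacegroup)
    return {tuple(canon[i]): intens[i] for i in range(len(canon))}, canon, intens


def _symmetry_related(h1: np.ndarray, h2: np.ndarray, rots: np.ndarray) -> bool:
    for r in rots:
        if np.array_equal(h1 @ r, h2):
            return True
    return False


def l_test(refls: ReflectionSet, pairing_radius: int = 2) -> TwinStats:
    """Local-pair intensity statistic L over non-symmetry-related neighbours.

    Pairs are (h, h + δ) for index offsets δ within the stencil
    0 ≤ δᵢ ≤ ``pairing_radius`` with odd component sum (which excludes every
    Friedel self-pairing); pairs related by a point-group operation are
    dropped. Needs at least 100 valid pairs.
    """
    lookup, canon, intens = _intensity_lookup(refls)
    rots = refls.spacegroup.point_group_rotations()
    offsets = [
        np.array(d)
        for d in itertools.product(range(pairing_radius + 1), repeat=3)
        if any(d) and sum(d) % 2 == 1
    ]
    hkl = refls.hkl
    lvals = []
    for d in offsets:
        h2 = hkl + d
        canon2 = canonical_hkl(h2, refls.spacegroup)
        i2 = np.array([lookup.get(tuple(c), np.nan) for c in canon2])
        valid = ~np.isnan(i2)
        for r in rots:  # drop pairs that are point-group mates
            valid &= ~np.all(hkl @ r == h2, axis=1)
        i2 = np.where(valid, i2, 0.0)
        valid &= intens + i2 > 0
        lvals.append((intens[valid] - i2[valid]) / (intens[valid] + i2[valid]))
    lv = np.concatenate(lvals) if lvals else np.empty(0)
    if len(lv) < 100:
        raise InsufficientPairsError(f"only {len(lv)} local pairs; need at least 100")
    return TwinStats(float(np.abs(lv).mean()), float((lv**2).mean()), len(lv))


def h_test(refls: ReflectionSet, twin_op: np.ndarray) -> TwinStats:
    """Twin-fraction estimate from twin-law-related intensity pairs.

    ``twin_op`` must be an integer index permutation that is an involution
    on the set (h·T·T = h and every image present). Fixed points
    (T·h = ±h up to point-group symmetry) are excluded. Returns moments of
    H and α̂ = 1/2 − ⟨H⟩ clipped to [0, 0.5].
    """
    op = np.asarray(twin_op, dtype=int)
    if op.shape != (3, 3):
        raise InvalidTwinOpError("twin operator must be a 3x3 integer matrix")
    if not np.array_equal(op @ op, np.eye(3, dtype=int)):
        raise InvalidTwinOpError("twin operator is not an involution")
    lookup, canon, intens = _intensity_lookup(refls)
    rots = refls.spacegroup.point_group_rotations()
    hkl = refls.hkl
    h2 = hkl @ op
    canon2 = canonical_hkl(h2, refls.spacegroup)
    hvals = []
    seen = set()
    for i in range(len(hkl)):
        key2 = tuple(canon2[i])
        if key2 not in lookup:
            raise InvalidTwinOpError(f"operator maps {tuple(hkl[i])} outside the set; not closed")
        if _symmetry_related(hkl[i], h2[i], rots):
            continue  # fixed point: twin op degenerates to symmetry here
        pair = frozenset((tuple(canon[i]), key2))
        if pair in seen:
            continue
        seen.add(pair)
        i1, i2 = intens[i], lookup[key2]
        if i1 + i2 <= 0:
            continue
        hvals.append(abs(i1 - i2) / (i1 + i2))
    if len(hvals) < 100:
        raise InsufficientPairsError(f"only {len(hvals)} twin-related pairs; need at least 100")
    hv = np.array(hvals)
    mean_h = float(hv.mean())
    if mean_h > 0.5:
        warnings.warn(f"<H> = {mean_h:.3f} > 1/2 (sampling noise); clipping alpha to 0", stacklevel=2)
    alpha = float(np.clip(0.5 - mean_h, 0.0, 0.5))
    return TwinStats(mean_h, float((hv**2).mean()), len(hv), alpha_hat=alpha)


def symmetrized_rmsd(
    model: StructureModel,
    subunit_chains: tuple,
    subunit_permutations: tuple | None = None,
    atom_filter=None,
) -> float:
    """R.m.s. deviation of a model from its symmetry-averaged version.

    The candidate point group is given as permutations of the subunit
    chains (default: the full cyclic group of the chain list). For each
    group element the permuted copy is rigid-body superposed onto the
    original (proper rotation only) and the superposed copies are averaged;
    the returned value is the r.m.s.d. between the original and averaged
    coordinates of the selected atoms (``atom_filter`` receives an
    :class:`AtomSite` and keeps the truthy ones, e.g. Cα only).

    Zero iff the model is exactly invariant under the candidate group.
    """
    m = len(subunit_chains)
    if subunit_permutations is None:
        subunit_permutations = tuple(tuple((j + s) % m for j in range(m)) for s in range(m))
    keep = atom_filter if atom_filter is not None else (lambda site: True)
    blocks = []
    for cid in subunit_chains:
        sites = [s for s in model.chains[cid] if keep(s)]
        blocks.append(model.cell.orthogonalize(np.array([s.position for s in sites])))
    counts = {b.shape[0] for b in blocks}
    if len(counts) != 1:
        raise XtaldeconError("subunits must have equal selected-atom counts for correspondence")
    coords = np.vstack(blocks)
    acc = np.zeros_like(coords)
    for perm in subunit_permutations:
        if sorted(perm) != list(range(m)):
            raise XtaldeconError(f"invalid subunit permutation {perm}")
        permuted = np.vstack([blocks[p] for p in perm])
        fit = superpose(permuted, coords)
        acc += fit.transform(permuted)
    symmetrized = acc / len(subunit_permutations)
    dev = coords - symmetrized
    return float(np.sqrt((dev**2).sum(axis=1).mean()))
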