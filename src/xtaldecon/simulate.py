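"""Synthetic layered-disorder crystals and twinned intensities.

The generator emulates a crystal built of well-ordered molecular layers
interleaved with a *sparse* layer: along the disorder axis, each column of
``period`` cells carries at most one sparse-layer molecule, sitting in one
of ``period`` lattice-translated slots (optionally in one of several
allowed orientations, or absent altogether), with the choices made
independently per column. Only the average structure diffracts coherently,
so the Bragg amplitudes of such a crystal are those of the ordered layer at
occupancy 1 plus the sparse molecule at occupancy (1 − void)/period — which
is exactly the collapsed supercell model the deconvolution procedure
recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cell import UnitCell
from .errors import IncompleteCoverageError, InsufficientSamplingError, XtaldeconError
from .model import AtomSite, StructureModel
from .reflections import ReflectionSet, canonical_hkl, generate_unique_hkl
from .scatter import fcalc_complex

__all__ = [
    "DisorderSpec",
    "CrystalRealization",
    "make_toy_molecule",
    "sample_realization",
    "simulate_bragg",
    "simulate_twin",
    "wilson_intensities",
]


def make_toy_molecule(n_atoms: int = 12, radius: float = 3.0, seed: int = 0) -> list:
    """Compact pseudo-random carbon cluster used as a stand-in molecule.

    Positions are Cartesian Å about the centroid (they are converted to
    cell fractions when the molecule is placed in a crystal); deterministic
    per seed.
    """
    if n_atoms < 1:
        raise XtaldeconError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    # rejection-free: uniform directions, radii biased to the surface region
    pts = rng.normal(size=(n_atoms, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= radius * rng.uniform(0.2, 1.0, size=(n_atoms, 1))
    pts -= pts.mean(axis=0)
    # renormalize so the farthest atom sits within the stated radius
    extent = np.linalg.norm(pts, axis=1).max()
    if extent > radius:
        pts *= radius / extent
    return [
        AtomSite(element="C", position=tuple(p), occupancy=1.0, b_factor=10.0, residue_id=i + 1)
        for i, p in enumerate(pts)
    ]


@dataclass
class DisorderSpec:
    """Full parameterization of a synthetic sparse-layer crystal.

    Defaults describe a small P1 toy crystal with a three-slot sparse layer
    (the period-3 pathology), uniform slot probabilities, no voids, a single
    allowed orientation and 5% multiplicative amplitude noise.
    """

    base_cell: UnitCell = field(default_factory=lambda: UnitCell(18.0, 22.0, 26.0))
    spacegroup: str = "P1"
    period: int = 3
    axis: str = "a"
    molecule: list = field(default_factory=lambda: make_toy_molecule(12, 3.0, seed=7))
    ordered_layer_placement: tuple = (0.25, 0.25, 0.25)
    sparse_layer_placement: tuple = (0.25, 0.70, 0.65)
    slot_probabilities: tuple | None = None  # uniform when None
    orientation_set: tuple = ()  # extra proper rotations; identity always allowed
    void_probability: float = 0.0
    amplitude_noise_fraction: float = 0.05
    n_realizations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period < 1:
            raise XtaldeconError("period must be >= 1")
        if not 0.0 <= self.void_probability < 1.0:
            raise XtaldeconError("void_probability must be in [0, 1)")
        if self.slot_probabilities is not None:
            p = np.asarray(self.slot_probabilities, dtype=float)
            if len(p) != self.period or abs(p.sum() - 1.0) > 1e-12 or (p < 0).any():
                raise XtaldeconError(
                    f"slot_probabilities must be {self.period} non-negative values summing to 1"
                )

    @property
    def slot_p(self) -> np.ndarray:
        if self.slot_probabilities is None:
            return np.full(self.period, 1.0 / self.period)
        return np.asarray(self.slot_probabilities, dtype=float)

    @property
    def orientations(self) -> list:
        """All allowed orientations of the sparse molecule (identity first)."""
        return [np.eye(3)] + [np.asarray(r, dtype=float) for r in self.orientation_set]

    def _placed_sites(self, placement, chain_id: str, occupancy: float, rotation=None) -> list:
        """Molecule placed at a fractional offset of the base cell."""
        cart = np.array([s.position for s in self.molecule])
        if rotation is not None:
            cart = cart @ np.asarray(rotation, dtype=float).T
        frac = self.base_cell.fractionalize(cart) + np.asarray(placement, dtype=float)
        return [
            replace(s, chain_id=chain_id, occupancy=occupancy, position=tuple(frac[i]))
            for i, s in enumerate(self.molecule)
        ]

    def average_model(self) -> StructureModel:
        """The coherently diffracting average structure in the base cell.

        Ordered chain A at occupancy 1; one sparse chain per allowed
        orientation (B, C, …) at occupancy (1 − void)/(period · n_orient).
        All slots are whole-cell translations along the disorder axis, so
        they coincide in the base cell.
        """
        chains = {"A": self._placed_sites(self.ordered_layer_placement, "A", 1.0)}
        orients = self.orientations
        occ = (1.0 - self.void_probability) / (self.period * len(orients))
        for i, rot in enumerate(orients):
            cid = chr(ord("B") + i)
            chains[cid] = self._placed_sites(self.sparse_layer_placement, cid, occ, rot)
        return StructureModel(self.base_cell, self.spacegroup, chains)


@dataclass
class CrystalRealization:
    """One random draw of the disordered crystal over several periods.

    ``slots[p]`` is the occupied slot of period p (−1 for a void) and
    ``orientations[p]`` the orientation index; the model spans
    period × n_periods base cells along the disorder axis in P1.
    """

    spec: DisorderSpec
    slots: np.ndarray
    orientations: np.ndarray

    @property
    def n_periods(self) -> int:
        return len(self.slots)

    @property
    def supercell_factor(self) -> int:
        return self.spec.period * self.n_periods

    def model(self) -> StructureModel:
        """Explicit all-atom model of this realization (P1 supercell)."""
        spec = self.spec
        m = self.supercell_factor
        cell = spec.base_cell.with_axis_scaled(spec.axis, m)
        ax = {"a": 0, "b": 1, "c": 2}[spec.axis]

        def to_super(frac_sites, cell_index, chain_id):
            out = []
            for s in frac_sites:
                pos = np.array(s.position)
                pos[ax] = (pos[ax] + cell_index) / m
                out.append(replace(s, chain_id=chain_id, occupancy=1.0, position=tuple(pos)))
            return out

        chains: dict = {}
        ordered = spec._placed_sites(spec.ordered_layer_placement, "A", 1.0)
        chains["A"] = [a for i in range(m) for a in to_super(ordered, i, "A")]
        sparse_atoms = []
        orients = spec.orientations
        for p in range(self.n_periods):
            if self.slots[p] < 0:
                continue
            placed = spec._placed_sites(
                spec.sparse_layer_placement, "B", 1.0, orients[self.orientations[p]]
            )
            sparse_atoms += to_super(placed, p * spec.period + int(self.slots[p]), "B")
        if sparse_atoms:
            chains["B"] = sparse_atoms
        return StructureModel(cell, "P1", chains)


def sample_realization(spec: DisorderSpec, n_periods: int = 1, seed: int | None = None) -> CrystalRealization:
    """Draw slots and orientations for ``n_periods`` independent columns."""
    if n_periods < 1:
        raise XtaldeconError("n_periods must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    void = rng.random(n_periods) < spec.void_probability
    slots = rng.choice(spec.period, size=n_periods, p=spec.slot_p)
    slots[void] = -1
    orientations = rng.integers(0, len(spec.orientations), size=n_periods)
    orientations[void] = 0
    return CrystalRealization(spec=spec, slots=slots, orientations=orientations)


def empirical_supercell_mean(
    spec: DisorderSpec, hkl_super: np.ndarray, n_realizations: int, seed: int = 0
) -> np.ndarray:
    """Mean complex supercell structure factor over seeded realizations.

    Reflections with index ≢ 0 mod period on the disorder axis carry only
    the diffuse (phase-averaged) component and converge to zero; sublattice
    reflections converge to period × the small-cell Bragg amplitude.
    Restricted to P1 specs: each column's disorder is independent, which a
    symmetry-constrained average cannot represent.
    """
    if spec.spacegroup not in ("P1", "P 1"):
        raise XtaldeconError("empirical averaging is implemented for P1 specs only")
    if n_realizations < 2:
        raise InsufficientSamplingError("empirical mode needs at least 2 realizations")
    acc = np.zeros(len(hkl_super), dtype=complex)
    for i in range(n_realizations):
        real = sample_realization(spec, n_periods=1, seed=(seed * 1_000_003 + i) % 2**31)
        acc += fcalc_complex(real.model(), hkl_super)
    return acc / n_realizations


def simulate_bragg(spec: DisorderSpec, d_min: float = 2.0, mode: str = "analytic") -> ReflectionSet:
    """Bragg amplitudes of the disordered crystal, in the base cell.

    analytic
        |F| of the average structure (exact coherent average).
    empirical
        |mean complex F| over ``spec.n_realizations`` seeded single-column
        realizations, computed in the period-fold supercell at the
        sublattice indices and rescaled to the base cell.

    Multiplicative Gaussian amplitude noise (fraction
    ``spec.amplitude_noise_fraction``, truncated at zero) is applied to
    f_obs; the sigma column is noise_fraction × amplitude.
    """
    from .symmetry import get_spacegroup

    sg = get_spacegroup(spec.spacegroup) if isinstance(spec.spacegroup, str) else spec.spacegroup
    refls = generate_unique_hkl(spec.base_cell, sg, d_min)
    if mode == "analytic":
        amp = np.abs(fcalc_complex(spec.average_model(), refls.hkl))
    elif mode == "empirical":
        ax = {"a": 0, "b": 1, "c": 2}[spec.axis]
        hkl_super = refls.hkl.copy()
        hkl_super[:, ax] *= spec.period
        mean_f = empirical_supercell_mean(spec, hkl_super, spec.n_realizations, seed=spec.seed)
        amp = np.abs(mean_f) / spec.period
    else:
        raise XtaldeconError(f"mode must be 'analytic' or 'empirical', got {mode!r}")
    rng = np.random.default_rng(spec.seed + 1)
    if spec.amplitude_noise_fraction > 0:
        amp = amp * np.maximum(0.0, 1.0 + spec.amplitude_noise_fraction * rng.standard_normal(len(amp)))
    out = refls.copy()
    out.data["f_obs"] = amp
    out.data["sigma"] = spec.amplitude_noise_fraction * amp
    out.data["observed"] = True
    return out


def simulate_twin(refls: ReflectionSet, twin_ops, fractions) -> ReflectionSet:
    """Twinned intensities I_twin(h) = Σ_i fraction_i · I(op_i · h).

    ``twin_ops`` are 3×3 integer index permutations (identity for the first
    individual is conventional but not required); every op must map the
    reflection set onto itself.
    """
    fr = np.asarray(fractions, dtype=float)
    if len(fr) != len(twin_ops) or (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise XtaldeconError("fractions must be non-negative, one per op, and sum to 1")
    intens = refls.intensities()
    if np.isnan(intens).any():
        raise XtaldeconError("reflection set carries no intensities (or f_obs) to twin")
    canon = canonical_hkl(refls.hkl, refls.spacegroup)
    lookup = {tuple(canon[i]): intens[i] for i in range(len(canon))}
    out_i = np.zeros(len(refls))
    for op, f in zip(twin_ops, fr):
        op = np.asarray(op, dtype=int)
        mapped = canonical_hkl(refls.hkl @ op, refls.spacegroup)
        for i, key in enumerate(map(tuple, mapped)):
            if key not in lookup:
                raise IncompleteCoverageError(
                    f"twin operator maps {tuple(refls.hkl[i])} outside the reflection set"
                )
            out_i[i] += f * lookup[key]
    out = refls.copy()
    out.data["intensity"] = out_i
    out.data["f_obs"] = np.sqrt(out_i)
    out.data["observed"] = True
    return out


def wilson_intensities(
    cell: UnitCell, spacegroup, d_min: float, seed: int = 0, mean_intensity: float = 1.0
) -> ReflectionSet:
    """Ideal untwinned acentric data: iid exponential intensities.

    The Wilson distribution of acentric intensities is exponential; drawing
    them independently per unique reflection gives the reference statistics
    of the twinning tests (⟨|L|⟩ = 1/2, ⟨L²⟩ = 1/3 untwinned).
    """
    from .symmetry import get_spacegroup

    sg = get_spacegroup(spacegroup) if isinstance(spacegroup, str) else spacegroup
    refls = generate_unique_hkl(cell, sg, d_min)
    rng = np.random.default_rng(seed)
    i = rng.exponential(mean_intensity, size=len(refls))
    refls.data["intensity"] = i
    refls.data["f_obs"] = np.sqrt(i)
    refls.data["observed"] = True
    return refls
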