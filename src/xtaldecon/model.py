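"""Atomic models: sites, chains, and symmetry expansion.

Coordinates are stored fractional (the cell owns the orthogonalization
convention); occupancies are per-site fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cell import UnitCell
from .errors import XtaldeconError
from .symmetry import SpaceGroupOps, get_spacegroup

__all__ = ["AtomSite", "StructureModel", "apply_symmetry"]


@dataclass(frozen=True)
class AtomSite:
    """One atom: element, fractional position, occupancy, isotropic B."""

    element: str
    position: tuple  # fractional (x, y, z)
    occupancy: float = 1.0
    b_factor: float = 15.0
    chain_id: str = "A"
    residue_id: int = 1
    atom_name: str = "C"

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise XtaldeconError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise XtaldeconError(f"negative B factor {self.b_factor}")
        object.__setattr__(self, "position", tuple(float(x) for x in self.position))


@dataclass
class StructureModel:
    """A crystal model: unit cell, space group, chains of atom sites.

    ``chains`` maps chain id → list of :class:`AtomSite`; insertion order is
    meaningful (it is the deposition order).
    """

    cell: UnitCell
    spacegroup: SpaceGroupOps
    chains: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.spacegroup, str):
            self.spacegroup = get_spacegroup(self.spacegroup)

    @property
    def chain_ids(self) -> list:
        return list(self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def all_sites(self) -> list:
        return [site for sites in self.chains.values() for site in sites]

    def positions(self, chain_id: str | None = None) -> np.ndarray:
        """(N, 3) fractional coordinates of one chain or the whole model."""
        sites = self.chains[chain_id] if chain_id else self.all_sites()
        if not sites:
            return np.empty((0, 3))
        return np.array([s.position for s in sites])

    def cartesian_positions(self, chain_id: str | None = None) -> np.ndarray:
        return self.cell.orthogonalize(self.positions(chain_id))

    def occupancies(self) -> np.ndarray:
        return np.array([s.occupancy for s in self.all_sites()])

    def with_chain_occupancy(self, chain_id: str, occupancy: float) -> "StructureModel":
        """Copy of the model with every site of one chain set to ``occupancy``."""
        chains = {
            cid: [replace(s, occupancy=occupancy) if cid == chain_id else s for s in sites]
            for cid, sites in self.chains.items()
        }
        return StructureModel(self.cell, self.spacegroup, chains)

    def copy(self) -> "StructureModel":
        return StructureModel(self.cell, self.spacegroup, {k: list(v) for k, v in self.chains.items()})


def apply_symmetry(model: StructureModel) -> list:
    """Expand a model to one copy per (operation × centring vector).

    Returns a flat list of :class:`AtomSite` with fractional coordinates
    reduced to [0, 1). Special positions are not merged.
    """
    sg = model.spacegroup
    out = []
    for site in model.all_sites():
        x = np.array(site.position)
        for op in sg.operations:
            base = op.apply(x)
            for cen in sg.centring_vectors():
                pos = np.mod(base + cen, 1.0)
                out.append(replace(site, position=tuple(pos)))
    return out
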