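"""File formats: PDB models (via gemmi), the plain-text HKL dialect, config.

The HKL dialect is whitespace-separated columns ``h k l f sigf fc phic free
obs`` with ``#`` comments; absent values are written as ``-``. Header
comments record the cell, space group and resolution limit so a file is
self-contained. Amplitudes round-trip to 6 significant figures.

PDB files use the fixed-column convention: Cartesian Å coordinates,
occupancy to 2 decimals (1/3 is written as 0.33), isotropic B; a CRYST1
record with a supported space-group symbol is required on input.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import yaml

from .cell import UnitCell
from .errors import FormatError
from .model import AtomSite, StructureModel
from .reflections import ReflectionSet, _empty_frame
from .symmetry import get_spacegroup

__all__ = ["read_pdb", "write_pdb", "read_hkl", "write_hkl", "RunConfig", "load_config"]


def write_pdb(model: StructureModel, path) -> None:
    """Write a model as fixed-column PDB (CRYST1 + ATOM records)."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(
        model.cell.a, model.cell.b, model.cell.c, model.cell.alpha, model.cell.beta, model.cell.gamma
    )
    st.spacegroup_hm = model.spacegroup.hm
    gm = gemmi.Model("1")
    for cid, sites in model.chains.items():
        chain = gemmi.Chain(cid)
        cart = model.cell.orthogonalize(np.array([s.position for s in sites]))
        res = None
        for i, s in enumerate(sites):
            if res is None or res.seqid.num != s.residue_id:
                res = gemmi.Residue()
                res.name = "UNK"
                res.seqid = gemmi.SeqId(str(s.residue_id))
                chain.add_residue(res)
                res = chain[-1]
            atom = gemmi.Atom()
            atom.name = s.atom_name
            atom.element = gemmi.Element(s.element)
            atom.pos = gemmi.Position(*cart[i])
            atom.occ = s.occupancy
            atom.b_iso = s.b_factor
            res.add_atom(atom)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(path) -> StructureModel:
    """Read a fixed-column PDB file into a fractional-coordinate model."""
    text = open(path).read()
    if "CRYST1" not in text:
        raise FormatError(f"{path}: missing CRYST1 record")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    c = st.cell
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    symbol = st.spacegroup_hm or ""
    if not symbol.strip():
        raise FormatError(f"{path}: CRYST1 record carries no space-group symbol")
    sg = get_spacegroup(symbol)  # raises UnsupportedGroupError when unknown
    chains: dict = {}
    for chain in st[0]:
        sites = []
        for res in chain:
            for atom in res:
                frac = cell.fractionalize([atom.pos.x, atom.pos.y, atom.pos.z])
                sites.append(
                    AtomSite(
                        element=atom.element.name,
                        position=tuple(frac),
                        occupancy=atom.occ,
                        b_factor=atom.b_iso,
                        chain_id=chain.name,
                        residue_id=res.seqid.num,
                        atom_name=atom.name,
                    )
                )
        chains[chain.name] = sites
    return StructureModel(cell, sg, chains)


_SENTINEL = "-"


def _fmt(value, spec="%.6g") -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return _SENTINEL
    return spec % value


def write_hkl(refls: ReflectionSet, path) -> None:
    """Write a reflection set in the plain-text HKL dialect."""
    cell = refls.cell
    with open(path, "w") as fh:
        fh.write("# xtaldecon HKL 1\n")
        fh.write(
            "# cell %.6f %.6f %.6f %.6f %.6f %.6f\n"
            % (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
        )
        fh.write(f"# spacegroup {refls.spacegroup.symbol}\n")
        if refls.d_min is not None:
            fh.write(f"# d_min {refls.d_min:.6g}\n")
        fh.write("# columns h k l f sigf fc phic free obs\n")
        d = refls.data
        for row in d.itertuples(index=False):
            free = _SENTINEL if row.free < 0 else str(int(row.free))
            fh.write(
                f"{row.h} {row.k} {row.l} {_fmt(row.f_obs)} {_fmt(row.sigma)} "
                f"{_fmt(row.f_calc)} {_fmt(row.phi_calc)} {free} {int(row.observed)}\n"
            )


def read_hkl(path) -> ReflectionSet:
    """Read the plain-text HKL dialect back into a :class:`ReflectionSet`."""
    cell = None
    sg = None
    d_min = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["cell"]:
                    cell = UnitCell(*(float(x) for x in parts[1:7]))
                elif parts[:1] == ["spacegroup"]:
                    sg = get_spacegroup(parts[1])
                elif parts[:1] == ["d_min"]:
                    d_min = float(parts[1])
                continue
            parts = line.split()
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            try:
                h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
                vals = [np.nan if p == _SENTINEL else float(p) for p in parts[3:7]]
                free = -1 if parts[7] == _SENTINEL else int(parts[7])
                obs = bool(int(parts[8]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            rows.append((h, k, l, *vals, free, obs))
    if cell is None or sg is None:
        raise FormatError(f"{path}: header must declare cell and spacegroup")
    frame = _empty_frame(len(rows))
    for i, col in enumerate(["h", "k", "l", "f_obs", "sigma", "f_calc", "phi_calc", "free", "observed"]):
        frame[col] = [r[i] for r in rows]
    frame["free"] = frame["free"].astype(np.int8)
    frame["observed"] = frame["observed"].astype(bool)
    return ReflectionSet(cell, sg, frame, d_min=d_min)


@dataclass
class RunConfig:
    """Resolved run configuration; every CLI run logs these values."""

    seed: int = 0
    d_min: float = 2.0
    axis: str = "a"
    factor: int = 3
    free_fraction: float = 0.05
    noise_fraction: float = 0.05

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in mapping.items() if k in known})


def load_config(path) -> dict:
    """Load a plain-text key-value (YAML subset) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be key-value pairs")
    return data
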