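"""Matthews coefficient and solvent content.

V_M = V_cell / (Z · n_chains · M_chain) with Z the general-position
multiplicity of the space group; the solvent fraction follows from the
conventional protein partial-specific volume via V_s = 1 − 1.230 / V_M.
"""

from __future__ import annotations

import warnings

from .cell import UnitCell
from .errors import XtaldeconError
from .symmetry import SpaceGroupOps

__all__ = ["matthews_solvent", "MATTHEWS_CONSTANT", "MEAN_RESIDUE_MASS"]

#: Conventional protein packing constant, Å³ per Da of protein per (Å³/Da).
MATTHEWS_CONSTANT = 1.230

#: Default mean residue mass (Da) used when only a residue count is known.
MEAN_RESIDUE_MASS = 110.0


def matthews_solvent(
    cell: UnitCell,
    sg: SpaceGroupOps,
    chains_per_asu: float,
    chain_mass: float,
    constant: float = MATTHEWS_CONSTANT,
):
    """Matthews volume (Å³/Da) and solvent fraction for one crystal form.

    Parameters
    ----------
    chains_per_asu
        Number of protein chains in the asymmetric unit; may be fractional
        for occupancy-weighted contents (e.g. 1.33 for one full chain plus
        a 1/3-occupied one).
    chain_mass
        Mass of one chain in Da.

    A solvent fraction outside [0, 1] is physically implausible; it is
    returned anyway, with a warning, so the caller can see how far off the
    inputs are.
    """
    if chain_mass <= 0:
        raise XtaldeconError(f"chain_mass must be positive, got {chain_mass}")
    if chains_per_asu <= 0:
        raise XtaldeconError(f"chains_per_asu must be positive, got {chains_per_asu}")
    vm = cell.volume / (sg.multiplicity * chains_per_asu * chain_mass)
    solvent = 1.0 - constant / vm
    if not 0.0 <= solvent <= 1.0:
        warnings.warn(
            f"solvent fraction {solvent:.3f} outside [0, 1]: implausible cell contents",
            stacklevel=2,
        )
    return vm, solvent
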