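"""Model builders shared by the supercell, simulator and acceptance tests."""

import numpy as np

import xtaldecon as xd


def random_two_chain_model(cell, spacegroup, seed, n_atoms=6):
    """Toy model with an ordered chain A and a sparse-candidate chain D.

    Atoms sit at general positions well inside the asymmetric region so no
    special-position logic is needed.
    """
    rng = np.random.default_rng(seed)
    elements = ["C", "N", "O", "S"]

    def sites(cid, lo, hi):
        return [
            xd.AtomSite(
                element=elements[i % len(elements)],
                position=tuple(lo + rng.random(3) * (hi - lo)),
                b_factor=float(5.0 + 10.0 * rng.random()),
                chain_id=cid,
                residue_id=i + 1,
            )
            for i in range(n_atoms)
        ]

    ordered = xd.StructureModel(cell, spacegroup, {"A": sites("A", 0.05, 0.30)})
    alt = xd.StructureModel(
        cell, spacegroup, {"A": ordered.chains["A"], "D": sites("D", 0.45, 0.70)}
    )
    return ordered, alt


def build_expanded(cell, spacegroup, n, seed):
    """Ordered+sparse model, its n-fold expansion, mapping and collapse roles."""
    ordered, alt = random_two_chain_model(cell, spacegroup, seed)
    mapping = xd.make_mapping(cell, "a", n)
    expanded = xd.expand_model(ordered, alt, mapping, anchor_chain="A", sparse_chains=("D",))
    roles = tuple(
        [xd.ChainRole(c, "ordered") for c in expanded.chain_ids[:n]]
        + [xd.ChainRole(expanded.chain_ids[n], "sparse")]
    )
    return ordered, expanded, mapping, roles
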