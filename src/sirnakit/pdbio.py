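"""Multi-model PDB round trip for conformational ensembles.

Frames map to MODEL/ENDMDL records (guide = chain G, passenger = chain
P, residue ids = 1-based strand positions).  On read, nonbonded
parameters are joined from the packaged table by (residue name, atom
name); an unresolvable atom raises an error naming it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .ensemble import ConformationEnsemble, Topology
from .params import ForceField, default_forcefield

__all__ = ["write_ensemble", "read_ensemble"]

_CHAIN = {"guide": "G", "passenger": "P"}
_ROLE = {v: k for k, v in _CHAIN.items()}


def write_ensemble(ens: ConformationEnsemble, path: str | Path) -> None:
    top = ens.topology
    n = top.n_atoms
    atoms = struc.AtomArray(n)
    atoms.chain_id = np.array([_CHAIN[str(r)] for r in top.roles])
    atoms.res_id = top.positions.astype(int)
    atoms.res_name = np.array([str(r) for r in top.resnames])
    atoms.atom_name = np.array([str(a) for a in top.names])
    atoms.element = np.array([str(e) for e in top.elements])
    atoms.hetero = np.zeros(n, dtype=bool)
    stack = struc.from_template(atoms, ens.frames.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ensemble(path: str | Path, ff: ForceField | None = None) -> ConformationEnsemble:
    """Read a (multi-model) PDB into an ensemble with joined parameters."""
    ff = ff or default_forcefield()
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    first = stack[0]
    names = np.array(first.atom_name, dtype=object)
    resnames = np.array(first.res_name, dtype=object)
    roles = np.array([_ROLE.get(c, "guide") for c in first.chain_id], dtype=object)
    positions = first.res_id.astype(int)
    # running residue index in file order
    resids = np.zeros(len(names), dtype=int)
    rid = -1
    prev = None
    for i in range(len(names)):
        key = (first.chain_id[i], int(first.res_id[i]))
        if key != prev:
            rid += 1
            prev = key
        resids[i] = rid
    assigned = ff.assign(resnames, names, resids)
    top = Topology(
        names=names,
        elements=assigned["elements"],
        resids=resids,
        resnames=resnames,
        roles=roles,
        positions=positions,
        charges=assigned["charges"],
        sigma=assigned["sigma"],
        epsilon=assigned["epsilon"],
        masses=assigned["masses"],
        radii=assigned["radii"],
    )
    return ConformationEnsemble(
        topology=top, frames=stack.coord.astype(float), provenance="file"
    )
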