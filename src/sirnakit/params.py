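"""Nonbonded parameter table: partial charges, Lennard-Jones, masses, radii.

The packaged table is an approximate, internally consistent parameter
set in the style of a standard nucleic-acid force field with added
2'-OMe / 2'-F entries.  Energies computed with it are meaningful
relative to each other within this package, not comparable to any
particular simulation force field.

By default each residue is neutralized at assignment time: the residue's
net charge is spread evenly over its heavy atoms.  This emulates
counterion condensation around the phosphate backbone so that strand to
strand electrostatics is not dominated by net-charge repulsion, while
hydrogen-bond polarity is preserved.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["ForceField", "load_forcefield", "VDW_RADII"]

FF_SHA256 = "765e8134a3ff09ab81193b5b05d1879e79c0ad03674be10c0be2677c643c1611"

#: van der Waals radii (Angstrom) used for SASA and volume
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "F": 1.47}


class ForceField:
    """Lookup of (residue name, atom name) -> nonbonded parameters."""

    def __init__(self, table: dict[tuple[str, str], tuple[str, float, float, float, float]]):
        self._table = table

    def lookup(self, resname: str, atom: str) -> tuple[str, float, float, float, float]:
        """Return (element, charge, sigma, epsilon, mass)."""
        try:
            return self._table[(resname, atom)]
        except KeyError:
            raise KeyError(
                f"no nonbonded parameters for atom {atom!r} in residue {resname!r}"
            ) from None

    def assign(
        self,
        resnames: np.ndarray,
        atomnames: np.ndarray,
        resids: np.ndarray,
        neutralize: bool = True,
    ) -> dict[str, np.ndarray]:
        """Vector parameter assignment for a whole topology.

        With ``neutralize`` (default), the net charge of each residue
        instance is subtracted evenly from its heavy atoms.
        """
        n = len(atomnames)
        out = {
            "elements": np.empty(n, dtype=object),
            "charges": np.empty(n),
            "sigma": np.empty(n),
            "epsilon": np.empty(n),
            "masses": np.empty(n),
            "radii": np.empty(n),
        }
        for i in range(n):
            el, q, sig, eps, mass = self.lookup(str(resnames[i]), str(atomnames[i]))
            out["elements"][i] = el
            out["charges"][i] = q
            out["sigma"][i] = sig
            out["epsilon"][i] = eps
            out["masses"][i] = mass
            out["radii"][i] = VDW_RADII[el]
        if neutralize:
            heavy = out["elements"] != "H"
            for rid in np.unique(resids):
                sel = resids == rid
                net = out["charges"][sel].sum()
                hsel = sel & heavy
                out["charges"][hsel] -= net / hsel.sum()
        return out


_DEFAULT_FF: ForceField | None = None


def load_forcefield(path: str | Path | None = None, check: bool = True) -> ForceField:
    if path is None:
        data = resources.files("sirnakit").joinpath("data/forcefield.tsv").read_bytes()
        if check and hashlib.sha256(data).hexdigest() != FF_SHA256:
            raise IOError("force-field table failed its checksum")
    else:
        data = Path(path).read_bytes()
    table: dict[tuple[str, str], tuple[str, float, float, float, float]] = {}
    for line in data.decode().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("residue\t"):
            continue
        res, atom, el, q, sig, eps, mass = line.split("\t")
        table[(res, atom)] = (el, float(q), float(sig), float(eps), float(mass))
    return ForceField(table)


def default_forcefield() -> ForceField:
    global _DEFAULT_FF
    if _DEFAULT_FF is None:
        _DEFAULT_FF = load_forcefield()
    return _DEFAULT_FF
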