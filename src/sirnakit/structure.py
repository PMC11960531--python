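"""Idealized A-form duplex builder and synthetic ensemble generator.

The builder stands in for molecular-dynamics trajectories: it places
Watson-Crick base-pair templates on an ideal fiber-geometry helix
(rise 2.81 A, twist 32.7 deg per step, pair planes normal to the axis),
attaches sugars in a chosen two-state pucker (C3'-endo / C2'-endo) at a
pucker-dependent glycosidic torsion, and realizes 2'-OMe / 2'-F / DNA
chemistry by swapping the 2' substituent atoms.  Base-pair geometry is
solved once per pair type by least squares against canonical
hydrogen-bond distance constraints, so every designed pair is
hydrogen-bondable under the package's detection criteria.

`synthesize_ensemble` draws statistically independent frames from a
built duplex: per-residue Bernoulli pucker flips honoring target
C2'-endo occupancies, terminal-pair fraying that displaces the terminal
guide base beyond hydrogen-bond range, and isotropic Gaussian thermal
noise.  No kinetics or solvent is emulated; frames are i.i.d.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from . import chemistry as chem
from .dataset import DuplexRecord, ModifiedStrand, Sugar, align_duplex
from .ensemble import ConformationEnsemble, SynthSpec, Topology
from .geometry import dihedral
from .params import ForceField, default_forcefield

__all__ = ["BuiltDuplex", "build_duplex", "synthesize_ensemble"]

RISE = 2.81  # A per base-pair step
TWIST = 32.7  # deg per step
GLYCOSIDIC_BOND = 1.475  # C1'-N, A
#: glycosidic torsion assigned per sugar pucker state (anti range)
CHI_BY_PUCKER = {"C3'-endo": -158.0, "C2'-endo": -100.0}
FRAY_DISPLACEMENT = 7.0  # A, shift of a frayed terminal guide base

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G", "T": "A"}
_PUCKER_TARGET_P = {"C3'-endo": 18.0, "C2'-endo": 162.0}


# ------------------------------------------------------------- small geometry

def _rot2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _rotz(theta_deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(theta_deg)), np.sin(np.radians(theta_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _axis_rotation(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = a
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(a, a)


def _align_x_to(u: np.ndarray) -> np.ndarray:
    """A rotation taking +x to unit vector u."""
    u = u / np.linalg.norm(u)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, u)
    c = float(np.dot(x, u))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else _axis_rotation(np.array([0.0, 0.0, 1.0]), 180.0)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * (1.0 / (1.0 + c))


# ------------------------------------------------------------- base templates

_HEX_SIDE = 1.38
_PENT_SIDE = 1.375
_B_CO = 1.23  # C=O
_B_CN = 1.34  # C-N amino
_B_CC = 1.50  # C-CH3
_B_CH = 1.08
_B_NH = 1.01


def _planar(xy: np.ndarray) -> np.ndarray:
    return np.array([xy[0], xy[1], 0.0])


def _build_base(letter: str) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Planar (z=0) base template; returns atoms and the in-plane unit
    direction of the glycosidic bond at N9/N1 (pointing away from the ring)."""
    hex_names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    ang = np.radians(60.0 * np.arange(6))
    hexagon = {n: _planar(_HEX_SIDE * np.array([np.cos(a), np.sin(a)])) for n, a in zip(hex_names, ang)}
    out = {n: hexagon[n] / np.linalg.norm(hexagon[n]) for n in hex_names}
    atoms = dict(hexagon)

    def rot_in_plane(v: np.ndarray, deg: float) -> np.ndarray:
        r = _rot2(np.radians(deg)) @ v[:2]
        return _planar(r)

    def methyl(center: np.ndarray, axis: np.ndarray, names: list[str]) -> None:
        a = axis / np.linalg.norm(axis)
        ref = np.array([0.0, 0.0, 1.0])
        p1 = ref - np.dot(ref, a) * a
        p1 /= np.linalg.norm(p1)
        p2 = np.cross(a, p1)
        alpha = np.radians(70.5)
        for k, nm in enumerate(names):
            az = np.radians(120.0 * k)
            d = a * np.cos(alpha) + (p1 * np.cos(az) + p2 * np.sin(az)) * np.sin(alpha)
            atoms[nm] = center + 1.09 * d

    if letter in chem.PURINES:
        c4, c5 = hexagon["C4"], hexagon["C5"]
        mid = 0.5 * (c4 + c5)
        u = mid / np.linalg.norm(mid)
        r5 = _PENT_SIDE / (2.0 * np.sin(np.radians(36.0)))
        center5 = mid + r5 * np.cos(np.radians(36.0)) * u

        def rot_about(p: np.ndarray, deg: float) -> np.ndarray:
            return center5 + _planar(_rot2(np.radians(deg)) @ (p - center5)[:2])

        sign = 1.0
        n9 = rot_about(c4, 72.0 * sign)
        if np.linalg.norm(n9) < np.linalg.norm(c4):  # wrong side: flip
            sign = -1.0
            n9 = rot_about(c4, 72.0 * sign)
        atoms["N9"] = n9
        atoms["C8"] = rot_about(c4, 144.0 * sign)
        atoms["N7"] = rot_about(c4, 216.0 * sign)
        pent_out = lambda n: (atoms[n] - center5) / np.linalg.norm(atoms[n] - center5)
        atoms["H8"] = atoms["C8"] + _B_CH * pent_out("C8")
        if letter == "A":
            atoms["N6"] = hexagon["C6"] + _B_CN * out["C6"]
            for nm, d in (("H61", 60.0), ("H62", -60.0)):
                atoms[nm] = atoms["N6"] + _B_NH * rot_in_plane(out["C6"], d)
            atoms["H2"] = hexagon["C2"] + _B_CH * out["C2"]
        else:  # G
            atoms["O6"] = hexagon["C6"] + _B_CO * out["C6"]
            atoms["H1"] = hexagon["N1"] + _B_NH * out["N1"]
            atoms["N2"] = hexagon["C2"] + _B_CN * out["C2"]
            for nm, d in (("H21", 60.0), ("H22", -60.0)):
                atoms[nm] = atoms["N2"] + _B_NH * rot_in_plane(out["C2"], d)
        glyc_dir = pent_out("N9")
    else:
        atoms["O2"] = hexagon["C2"] + _B_CO * out["C2"]
        atoms["H6"] = hexagon["C6"] + _B_CH * out["C6"]
        if letter == "C":
            atoms["N4"] = hexagon["C4"] + _B_CN * out["C4"]
            for nm, d in (("H41", 60.0), ("H42", -60.0)):
                atoms[nm] = atoms["N4"] + _B_NH * rot_in_plane(out["C4"], d)
            atoms["H5"] = hexagon["C5"] + _B_CH * out["C5"]
        else:  # U or T
            atoms["H3"] = hexagon["N3"] + _B_NH * out["N3"]
            atoms["O4"] = hexagon["C4"] + _B_CO * out["C4"]
            if letter == "U":
                atoms["H5"] = hexagon["C5"] + _B_CH * out["C5"]
            else:  # T
                atoms["C7"] = hexagon["C5"] + _B_CC * out["C5"]
                methyl(atoms["C7"], out["C5"], ["H71", "H72", "H73"])
        glyc_dir = out["N1"]
    return atoms, glyc_dir


#: Watson-Crick constraints (purine atom, pyrimidine atom, target A).
#: Heavy-atom spacings set the register, donor-H-to-acceptor spacings
#: enforce near-linear hydrogen bonds, and the glycosidic-N spacing
#: fixes the frame.  Amino groups carry two hydrogens; ``|``-separated
#: names mean "either one", resolved by trying both and keeping the
#: best-fitting pose.
_WC_CONSTRAINTS = {
    ("A", "U"): [
        ("N1", "N3", 2.82),
        ("N1", "H3", 1.81),
        ("N6", "O4", 2.95),
        ("H61|H62", "O4", 1.94),
        ("N9", "N1", 8.95),
    ],
    ("A", "T"): [
        ("N1", "N3", 2.82),
        ("N1", "H3", 1.81),
        ("N6", "O4", 2.95),
        ("H61|H62", "O4", 1.94),
        ("N9", "N1", 8.95),
    ],
    ("G", "C"): [
        ("O6", "N4", 2.91),
        ("O6", "H41|H42", 1.90),
        ("N1", "N3", 2.95),
        ("H1", "N3", 1.94),
        ("N2", "O2", 2.86),
        ("H21|H22", "O2", 1.85),
        ("N1", "O2", 3.65),  # keeps the central bond from bifurcating
        ("N9", "N1", 8.95),
    ],
}


@lru_cache(maxsize=None)
def _raw_pair(purine: str, pyrimidine: str):
    """Pair template with purine on -x, pyrimidine on +x, bases in z=0.

    Returns (pur_atoms, pyr_atoms, pur_glyc_dir, pyr_glyc_dir)."""
    pur, pur_dir = _build_base(purine)
    pyr, pyr_dir = _build_base(pyrimidine)

    glyc_n = chem.GLYCOSIDIC_N[purine]

    # expand "either amino hydrogen" alternatives into concrete sets
    con_sets = [[]]
    for a, b, t in _WC_CONSTRAINTS[(purine, pyrimidine)]:
        expanded = []
        for aa in a.split("|"):
            for bb in b.split("|"):
                expanded.append((aa, bb, t))
        con_sets = [cs + [e] for cs in con_sets for e in expanded]

    def transform(params, pts):
        th, tx, ty = params
        R = _rot2(th)
        return pts @ R.T + np.array([tx, ty])

    pyr_xy = np.array([pyr[a][:2] for a in pyr])
    names = list(pyr)

    heavy = [n for n in names if not n.startswith("H")]
    pur_heavy = np.array([pur[n][:2] for n in pur if not n.startswith("H")])
    heavy_rows = np.array([names.index(n) for n in heavy])

    def acceptable(params) -> bool:
        moved = transform(params, pyr_xy)
        d = np.linalg.norm(
            pur_heavy[:, None, :] - moved[heavy_rows][None, :, :], axis=2
        )
        return bool(d.min() > 1.5)  # reject ring-overlap branches

    best = None
    t0 = pur[glyc_n][:2] + np.array([8.95, 0.0]) - pyr[chem.GLYCOSIDIC_N[pyrimidine]][:2]
    def weight(a: str, b: str) -> float:
        # hydrogen-bond linearity is weighted up so donor-H vectors aim
        # at their acceptors; the glycosidic frame spacing is soft
        if a.startswith("H") or b.startswith("H"):
            return 3.0
        if a == glyc_n and b == chem.GLYCOSIDIC_N[pyrimidine]:
            return 0.5
        return 1.0

    for cons in con_sets:

        def resid(params, cons=cons):
            moved = transform(params, pyr_xy)
            pos = {n: moved[i] for i, n in enumerate(names)}
            return [
                weight(a, b) * (np.linalg.norm(pur[a][:2] - pos[b]) - t)
                for a, b, t in cons
            ]

        for th0 in np.radians(np.arange(0, 360, 30)):
            sol = least_squares(resid, x0=[th0, t0[0], t0[1]])
            if not acceptable(sol.x):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    # idealized ring polygons cannot satisfy every (weighted) constraint
    # exactly; residuals of ~0.1 A per constraint are acceptable
    if best is None or best.cost > 0.5:
        raise RuntimeError(f"pair optimization failed for {purine}:{pyrimidine}")
    moved = transform(best.x, pyr_xy)
    pyr = {n: _planar(moved[i]) for i, n in enumerate(names)}
    pyr_dir = _planar(_rot2(best.x[0]) @ pyr_dir[:2])

    # canonical frame: glycosidic-N midpoint at origin, purine->pyr along +x
    a = pur[glyc_n]
    b = pyr[chem.GLYCOSIDIC_N[pyrimidine]]
    mid = 0.5 * (a + b)
    xdir = (b - a) / np.linalg.norm(b - a)
    th = -np.arctan2(xdir[1], xdir[0])
    R = _rot2(th)

    def canon(p):
        return _planar(R @ (p - mid)[:2])

    def canon_dir(d):
        return _planar(R @ d[:2])

    pur = {k: canon(v) for k, v in pur.items()}
    pyr = {k: canon(v) for k, v in pyr.items()}
    return pur, pyr, canon_dir(pur_dir), canon_dir(pyr_dir)


def _pair_for_guide(guide_letter: str):
    """(guide_atoms, passenger_atoms, guide_dir, passenger_dir) with the
    guide base on the -x side of the canonical pair frame."""
    if guide_letter in chem.PURINES:
        partner = _COMP[guide_letter]
        pur, pyr, pd, yd = _raw_pair(guide_letter, partner)
        return pur, pyr, pd, yd
    purine = _COMP[guide_letter]
    pur, pyr, pd, yd = _raw_pair(purine, guide_letter)
    # swap strand roles by a 180-degree rotation about the helix axis
    flip = lambda p: np.array([-p[0], -p[1], p[2]])
    g = {k: flip(v) for k, v in pyr.items()}
    p = {k: flip(v) for k, v in pur.items()}
    return g, p, flip(yd), flip(pd)


# ------------------------------------------------------------ sugar templates

_SUGAR_RING_SIDE = 1.50
_PUCKER_AMPLITUDE_Z = 0.25  # out-of-plane displacement amplitude, A


def _local_pseudorotation(ring: dict[str, np.ndarray]) -> float:
    order = [
        ("C4'", "O4'", "C1'", "C2'"),
        ("O4'", "C1'", "C2'", "C3'"),
        ("C1'", "C2'", "C3'", "C4'"),
        ("C2'", "C3'", "C4'", "O4'"),
        ("C3'", "C4'", "O4'", "C1'"),
    ]
    nus = [dihedral(ring[a], ring[b], ring[c], ring[d]) for a, b, c, d in order]
    num = (nus[4] + nus[1]) - (nus[3] + nus[0])
    den = 2.0 * nus[2] * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))
    P = np.degrees(np.arctan2(num, den))
    return P + 360.0 if P < 0 else P


def _puckered_ring(phase: float) -> dict[str, np.ndarray]:
    names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    r = _SUGAR_RING_SIDE / (2.0 * np.sin(np.radians(36.0)))
    ring = {}
    for j, nm in enumerate(names):
        a = np.radians(72.0 * j)
        z = _PUCKER_AMPLITUDE_Z * np.cos(4.0 * np.pi * j / 5.0 + phase)
        ring[nm] = np.array([r * np.cos(a), r * np.sin(a), z])
    return ring


@lru_cache(maxsize=None)
def _ring_phase_for(pucker: str) -> float:
    """Pucker-pattern phase whose ring classifies at the target P."""
    target = _PUCKER_TARGET_P[pucker]
    phases = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    best, bestd = 0.0, 1e9
    for ph in phases:
        P = _local_pseudorotation(_puckered_ring(ph))
        d = abs((P - target + 180.0) % 360.0 - 180.0)
        if d < bestd:
            best, bestd = ph, d
    return float(best)


def _bent(prev: np.ndarray, cur: np.ndarray, length: float, angle_deg: float, ref: np.ndarray) -> np.ndarray:
    """Point at `length` from `cur` with bond angle prev-cur-new = angle,
    bent toward `ref`."""
    d0 = (cur - prev) / np.linalg.norm(cur - prev)
    p = ref - np.dot(ref, d0) * d0
    if np.linalg.norm(p) < 1e-9:
        p = np.array([0.0, 0.0, 1.0]) - d0[2] * d0
    p /= np.linalg.norm(p)
    a = np.radians(180.0 - angle_deg)
    return cur + length * (d0 * np.cos(a) + p * np.sin(a))


def _three_around(prev: np.ndarray, cur: np.ndarray, lengths: list[float], ref: np.ndarray) -> list[np.ndarray]:
    """Three tetrahedral branches from `cur` away from `prev`, the first
    aimed toward `ref`."""
    a = (cur - prev) / np.linalg.norm(cur - prev)
    p1 = ref - np.dot(ref, a) * a
    if np.linalg.norm(p1) < 1e-9:
        p1 = np.array([0.0, 0.0, 1.0]) - a[2] * a
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(a, p1)
    alpha = np.radians(70.5)
    pts = []
    for k, L in enumerate(lengths):
        az = np.radians(120.0 * k)
        d = a * np.cos(alpha) + (p1 * np.cos(az) + p2 * np.sin(az)) * np.sin(alpha)
        pts.append(cur + L * d)
    return pts


@lru_cache(maxsize=None)
def _sugar_template(sugar: Sugar, pucker: str) -> dict[str, np.ndarray]:
    """Full sugar+backbone template: C1' at origin, glycosidic bond along +x.

    Includes P/OP1/OP2 and HO5'/HO3' variants; the assembler selects the
    subset each residue actually carries.
    """
    ring = _puckered_ring(_ring_phase_for(pucker))
    atoms = dict(ring)
    order = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    # mean-plane normal ("up" side carries the base at C1')
    xyz = np.array([ring[n] for n in order])
    c = xyz.mean(axis=0)
    _u, _s, vt = np.linalg.svd(xyz - c)
    n_up = vt[2] if vt[2][2] > 0 else -vt[2]

    def exo_dirs(center: str) -> tuple[np.ndarray, np.ndarray]:
        i = order.index(center)
        a = ring[order[(i - 1) % 5]] - ring[center]
        b = ring[order[(i + 1) % 5]] - ring[center]
        a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
        bis = -(a + b)
        bis /= np.linalg.norm(bis)
        ax = np.cross(a, b)
        ax /= np.linalg.norm(ax)
        if np.dot(ax, n_up) < 0:
            ax = -ax
        up = bis + ax
        dn = bis - ax
        return up / np.linalg.norm(up), dn / np.linalg.norm(dn)

    up1, dn1 = exo_dirs("C1'")
    atoms["N*"] = ring["C1'"] + GLYCOSIDIC_BOND * up1  # glycosidic attachment marker
    atoms["H1'"] = ring["C1'"] + 1.09 * dn1
    up2, dn2 = exo_dirs("C2'")
    atoms["H2'"] = ring["C2'"] + 1.09 * up2
    if sugar in (Sugar.OH, Sugar.OME):
        # the hydroxyl hydrogen / methyl group is attached in world
        # space so it can point into solvent (minor groove)
        atoms["O2'"] = ring["C2'"] + 1.41 * dn2
    elif sugar is Sugar.F:
        atoms["F2'"] = ring["C2'"] + 1.38 * dn2
    else:  # deoxyribose
        atoms["H2''"] = ring["C2'"] + 1.09 * dn2
    up3, dn3 = exo_dirs("C3'")
    atoms["H3'"] = ring["C3'"] + 1.09 * up3
    atoms["O3'"] = ring["C3'"] + 1.42 * dn3
    up4, dn4 = exo_dirs("C4'")
    atoms["C5'"] = ring["C4'"] + 1.51 * up4
    atoms["H4'"] = ring["C4'"] + 1.09 * dn4

    # canonical frame: C1' at origin, C1'->N along +x.  The 5' branch
    # beyond C5' and the O3'/O5' hydrogens are built in world space so
    # the phosphates can be aimed away from the helix interior.
    origin = ring["C1'"].copy()
    R = _align_x_to(atoms["N*"] - origin).T  # maps (N - C1') to +x
    return {k: R @ (v - origin) for k, v in atoms.items()}


# ---------------------------------------------------------------- duplex build

@dataclass
class BuiltDuplex:
    """A built single-frame duplex plus the variant data the synthetic
    ensemble generator needs (per-residue pucker alternates and
    terminal-fray displacement vectors)."""

    ensemble: ConformationEnsemble
    sugar_variants: dict[tuple[str, int], dict[str, np.ndarray]]
    sugar_indices: dict[tuple[str, int], np.ndarray]
    fray_vectors: dict[int, tuple[np.ndarray, np.ndarray]]  # pair -> (indices, shift)

    @property
    def topology(self) -> Topology:
        return self.ensemble.topology

    @property
    def coords(self) -> np.ndarray:
        return self.ensemble.frames[0]


def _helix_op(pair_index: int) -> tuple[np.ndarray, np.ndarray]:
    R = _rotz((pair_index - 1) * TWIST)
    t = np.array([0.0, 0.0, (pair_index - 1) * RISE])
    return R, t


def _sugar_for(nt) -> Sugar:
    return nt.sugar


def _place_sugar(
    sugar: Sugar,
    pucker: str,
    n_world: np.ndarray,
    glyc_dir: np.ndarray,
    chi_ref_world: np.ndarray,
) -> dict[str, np.ndarray]:
    """Place the sugar template so C1' sits along the glycosidic direction
    and the torsion O4'-C1'-N-ref equals the pucker's chi value."""
    tmpl = _sugar_template(sugar, pucker)
    c1_world = n_world + GLYCOSIDIC_BOND * glyc_dir
    u = (n_world - c1_world) / np.linalg.norm(n_world - c1_world)
    R0 = _align_x_to(u)
    placed = {k: c1_world + R0 @ v for k, v in tmpl.items()}
    chi_now = dihedral(placed["O4'"], placed["C1'"], n_world, chi_ref_world)
    target = CHI_BY_PUCKER[pucker]
    delta = target - chi_now
    for sign in (1.0, -1.0):
        Rs = _axis_rotation(u, sign * delta)
        test = {k: c1_world + Rs @ (v - c1_world) for k, v in placed.items()}
        got = dihedral(test["O4'"], test["C1'"], n_world, chi_ref_world)
        if abs((got - target + 180.0) % 360.0 - 180.0) < 1e-6:
            placed = test
            break
    else:  # pragma: no cover
        raise RuntimeError("chi placement failed")
    del placed["N*"]

    # 5' branch and terminal hydroxyl hydrogens, aimed radially outward
    # from the helix axis (global z) to keep phosphates on the outside
    c5, c4, c3, o3 = placed["C5'"], placed["C4'"], placed["C3'"], placed["O3'"]
    radial = np.array([c5[0], c5[1], 0.0])
    nr = np.linalg.norm(radial)
    radial = radial / nr if nr > 1e-9 else np.array([1.0, 0.0, 0.0])
    o5p, h5a, h5b = _three_around(c4, c5, [1.44, 1.09, 1.09], radial)
    placed["O5'"], placed["H5'"], placed["H5''"] = o5p, h5a, h5b
    placed["P"] = _bent(c5, o5p, 1.60, 120.0, radial)
    op1, op2, _unused = _three_around(o5p, placed["P"], [1.48, 1.48, 1.48], radial)
    placed["OP1"], placed["OP2"] = op1, op2
    placed["HO5'"] = _bent(c5, o5p, 0.96, 110.0, radial)
    placed["HO3'"] = _bent(c3, o3, 0.96, 109.5, radial)
    if "O2'" in placed:
        c2, o2 = placed["C2'"], placed["O2'"]
        if sugar is Sugar.OH:
            placed["HO2'"] = _bent(c2, o2, 0.96, 109.5, radial)
        else:  # 2'-OMe methyl projects into solvent
            placed["CM2"] = _bent(c2, o2, 1.41, 113.0, radial)
            for nm, p in zip(
                ["HM21", "HM22", "HM23"],
                _three_around(o2, placed["CM2"], [1.09, 1.09, 1.09], radial),
            ):
                placed[nm] = p
    return placed


def build_duplex(
    duplex: DuplexRecord,
    pucker_state: dict[tuple[str, int], str] | None = None,
    ff: ForceField | None = None,
) -> BuiltDuplex:
    """Build an idealized A-form structure of a validated duplex.

    ``pucker_state`` maps (role, position) to "C3'-endo" or "C2'-endo";
    unlisted residues default to the free-energy-minimum C3'-endo.
    """
    aln = align_duplex(duplex.guide, duplex.passenger)
    if not aln.valid:
        raise ValueError(f"{duplex.duplex_id}: cannot build mismatched duplex {aln.mismatches}")
    ff = ff or default_forcefield()
    pucker_state = pucker_state or {}

    names, resnames, resids, roles, positions = [], [], [], [], []
    coords: list[np.ndarray] = []
    sugar_indices: dict[tuple[str, int], np.ndarray] = {}
    sugar_variants: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    residue_atom_slices: dict[tuple[str, int], slice] = {}
    rid = 0

    def base_placement(role: str, position: int):
        """World base atoms + glycosidic info for one residue."""
        if role == "guide":
            pair_index = position
            if position <= 19:
                letter = duplex.guide.residues[position - 1].base
                g, _p, gdir, _pdir = _pair_for_guide(letter)
                atoms, adir = g, gdir
            else:  # dT overhang continues the guide track
                g, _p, gdir, _pdir = _pair_for_guide("T")
                atoms, adir = g, gdir
        else:
            pair_index = 20 - position
            if position <= 19:
                letter = duplex.guide.residues[pair_index - 1].base
                _g, p, _gdir, pdir = _pair_for_guide(letter)
                atoms, adir = p, pdir
            else:  # passenger dT overhang: passenger side of an A:T frame
                _pur, pyr, _pd, yd = _raw_pair("A", "T")
                atoms, adir = pyr, yd
        R, t = _helix_op(pair_index)
        world = {k: R @ v + t for k, v in atoms.items()}
        return world, R @ adir

    for strand, role in ((duplex.guide, "guide"), (duplex.passenger, "passenger")):
        for nt in strand.residues:
            resname = chem.resname_for(nt)
            letter = nt.base
            world_base, glyc_dir = base_placement(role, nt.position)
            n_name = chem.GLYCOSIDIC_N[letter]
            chi_ref = chem.CHI_REF_ATOM[letter]
            pucker = pucker_state.get((role, nt.position), "C3'-endo")
            five_p = nt.position == 1
            three_p = nt.position == len(strand)
            sugar_names = chem.sugar_atoms(resname, five_p, three_p)
            both = {}
            for pk in ("C3'-endo", "C2'-endo"):
                placed = _place_sugar(
                    nt.sugar, pk, world_base[n_name], glyc_dir, world_base[chi_ref]
                )
                both[pk] = np.array([placed[a] for a in sugar_names])
            start = len(names)
            for a in sugar_names:
                names.append(a)
            coords.extend(both[pucker])
            for a in chem.base_atoms(resname):
                names.append(a)
                coords.append(world_base[a])
            stop = len(names)
            n_res_atoms = stop - start
            resnames.extend([resname] * n_res_atoms)
            resids.extend([rid] * n_res_atoms)
            roles.extend([role] * n_res_atoms)
            positions.extend([nt.position] * n_res_atoms)
            key = (role, nt.position)
            sugar_indices[key] = np.arange(start, start + len(sugar_names))
            sugar_variants[key] = both
            residue_atom_slices[key] = slice(start, stop)
            rid += 1

    names_a = np.array(names, dtype=object)
    resnames_a = np.array(resnames, dtype=object)
    resids_a = np.array(resids, dtype=int)
    assigned = ff.assign(resnames_a, names_a, resids_a)
    top = Topology(
        names=names_a,
        elements=assigned["elements"],
        resids=resids_a,
        resnames=resnames_a,
        roles=np.array(roles, dtype=object),
        positions=np.array(positions, dtype=int),
        charges=assigned["charges"],
        sigma=assigned["sigma"],
        epsilon=assigned["epsilon"],
        masses=assigned["masses"],
        radii=assigned["radii"],
    )
    xyz = np.array(coords)

    fray_vectors: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for pair in (1, 19):
        key = ("guide", pair)
        sl = residue_atom_slices[key]
        _wb, gdir = base_placement("guide", pair)
        fray_vectors[pair] = (
            np.arange(sl.start, sl.stop),
            FRAY_DISPLACEMENT * gdir,
        )

    ens = ConformationEnsemble(topology=top, frames=xyz[None], provenance="built")
    return BuiltDuplex(
        ensemble=ens,
        sugar_variants=sugar_variants,
        sugar_indices=sugar_indices,
        fray_vectors=fray_vectors,
    )


# ----------------------------------------------------------- ensemble synthesis

def synthesize_ensemble(built: BuiltDuplex, spec: SynthSpec) -> ConformationEnsemble:
    """Draw statistically independent frames from a built duplex.

    Per frame and residue, the sugar is C2'-endo with the residue's
    target occupancy (else C3'-endo); each terminal core pair opens with
    probability ``fray_prob`` (its guide base displaced beyond
    hydrogen-bond range); isotropic Gaussian noise of width
    ``positional_noise_sigma`` is added to every atom.  Identical
    (duplex, spec, seed) give bit-identical frames.
    """
    rng = np.random.default_rng(spec.seed)
    base = built.ensemble.frames[0]
    n = spec.n_frames
    frames = np.repeat(base[None], n, axis=0)
    for key in sorted(built.sugar_variants):
        occ = spec.occupancy_for(*key)
        idx = built.sugar_indices[key]
        variants = built.sugar_variants[key]
        # set the default state everywhere, then flip the sampled frames
        frames[:, idx] = variants["C3'-endo"]
        if occ > 0.0:
            flips = np.flatnonzero(rng.random(n) < occ)
            if len(flips):
                frames[np.ix_(flips, idx)] = variants["C2'-endo"]
    if spec.fray_prob > 0.0:
        for pair in sorted(built.fray_vectors):
            idx, shift = built.fray_vectors[pair]
            open_frames = np.flatnonzero(rng.random(n) < spec.fray_prob)
            if len(open_frames):
                frames[np.ix_(open_frames, idx)] += shift
    if spec.positional_noise_sigma > 0.0:
        frames += rng.normal(0.0, spec.positional_noise_sigma, size=frames.shape)
    return ConformationEnsemble(
        topology=built.topology,
        frames=frames,
        provenance="synthetic",
    )
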