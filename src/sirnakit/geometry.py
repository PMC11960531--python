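"""Geometric trajectory features: superposition, distances, hydrogen bonds,
base pairing/stacking, surface area, volume, sugar pucker and glycosidic
torsions.

All features are functions of atom coordinates plus the topology's atom
identities; they are invariant under global rotation and translation of
a frame.  Thresholds follow common structural-biology practice and are
exposed as keyword arguments: hydrogen bonds at donor-acceptor <= 3.5 A
and donor-H...acceptor angle >= 135 deg, stacking at ring-centroid
distance <= 4.5 A with inter-normal angle <= 30 deg, solvent probe
1.4 A on a 960-point deterministic sphere lattice, volume voxels 0.5 A.
"""

from __future__ import annotations

import numpy as np

from .chemistry import (
    BASE_RING_ATOMS,
    CHI_REF_ATOM,
    GLYCOSIDIC_N,
    base_atoms,
    base_letter,
)
from .ensemble import ConformationEnsemble, Topology

__all__ = [
    "kabsch_rotation",
    "kabsch_rmsd",
    "end_to_end",
    "detect_hbonds",
    "count_base_pairs",
    "count_base_stacks",
    "sasa",
    "volume_density",
    "dihedral",
    "pseudorotation",
    "classify_pucker",
    "chi_dihedral",
]

AMU_TO_G_PER_ML = 1.66054  # 1 amu/A^3 in g/mL


# ---------------------------------------------------------------- superposition

def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation mapping centered P onto centered Q.

    Returns (R, centroid_P, centroid_Q) with proper rotation R (det +1)
    from the covariance-SVD construction.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must both have shape (n, 3)")
    if len(P) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cp, cq


def kabsch_rmsd(frame: np.ndarray, reference: np.ndarray, selection: np.ndarray | None = None) -> float:
    """Minimal RMSD (Angstrom) of frame vs reference over rigid motions."""
    P = np.asarray(frame, float)
    Q = np.asarray(reference, float)
    if selection is not None:
        P, Q = P[selection], Q[selection]
    R, cp, cq = kabsch_rotation(P, Q)
    moved = (P - cp) @ R.T + cq
    return float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))


# ------------------------------------------------------------------- distances

def _base_atom_indices(top: Topology, role: str, position: int) -> np.ndarray:
    sel = top.atom_indices(role=role, position=position)
    resname = str(top.resnames[sel[0]])
    names = set(base_atoms(resname))
    return sel[np.isin(top.names[sel], list(names))]


def end_to_end(top: Topology, coords: np.ndarray, n_core: int = 19) -> float:
    """Distance between the mass centers of the two terminal core pairs.

    The terminal pairs of an n_core-bp duplex are (g1, p[n_core]) and
    (g[n_core], p1); only base atoms enter the centers of mass.
    """
    def pair_com(gpos: int, ppos: int) -> np.ndarray:
        idx = np.concatenate(
            [
                _base_atom_indices(top, "guide", gpos),
                _base_atom_indices(top, "passenger", ppos),
            ]
        )
        m = top.masses[idx]
        return (coords[idx] * m[:, None]).sum(axis=0) / m.sum()

    return float(np.linalg.norm(pair_com(1, n_core) - pair_com(n_core, 1)))


# -------------------------------------------------------------- hydrogen bonds

def _donor_pairs(top: Topology, coords: np.ndarray) -> list[tuple[int, int]]:
    """(heavy, H) pairs with H within covalent range of N/O.

    The 1.4 A cutoff tolerates thermal jitter of the generator while
    staying far below any nonbonded H...heavy contact (>= 1.8 A)."""
    h_idx = np.flatnonzero(top.elements == "H")
    heavy_idx = np.flatnonzero(top.elements != "H")
    pairs = []
    for h in h_idx:
        d = np.linalg.norm(coords[heavy_idx] - coords[h], axis=1)
        j = np.argmin(d)
        # the bonded partner is the nearest heavy atom; only N-H / O-H
        # hydrogens are donors (carbon-bound hydrogens never are)
        if d[j] <= 1.4 and str(top.elements[heavy_idx[j]]) in ("N", "O"):
            pairs.append((int(heavy_idx[j]), int(h)))
    return pairs


def detect_hbonds(
    top: Topology,
    coords: np.ndarray,
    d_max: float = 3.5,
    angle_min: float = 135.0,
) -> list[tuple[int, int, int]]:
    """All (donor, H, acceptor) triples meeting the geometric criteria.

    Donors are N-H / O-H groups; acceptors are N, O or F atoms carrying
    no hydrogen.  Intra-residue contacts are excluded.  Both thresholds
    are closed (values exactly at the boundary count).
    """
    donors = _donor_pairs(top, coords)
    donor_heavies = {d for d, _h in donors}
    acc_mask = np.isin(top.elements, ["N", "O", "F"])
    acceptors = np.array(
        [i for i in np.flatnonzero(acc_mask) if i not in donor_heavies], dtype=int
    )
    if len(acceptors) == 0 or not donors:
        return []
    out = []
    acc_xyz = coords[acceptors]
    for heavy, h in donors:
        dvec = acc_xyz - coords[heavy]
        dist = np.linalg.norm(dvec, axis=1)
        cand = np.flatnonzero(
            (dist <= d_max) & (top.resids[acceptors] != top.resids[heavy])
        )
        for k in cand:
            a = int(acceptors[k])
            v1 = coords[heavy] - coords[h]
            v2 = coords[a] - coords[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang >= angle_min:
                out.append((heavy, h, a))
    return out


def _base_mask(top: Topology) -> np.ndarray:
    mask = np.zeros(top.n_atoms, dtype=bool)
    for rid in np.unique(top.resids):
        sel = np.flatnonzero(top.resids == rid)
        names = set(base_atoms(str(top.resnames[sel[0]])))
        mask[sel[np.isin(top.names[sel], list(names))]] = True
    return mask


def count_base_pairs(
    top: Topology,
    coords: np.ndarray,
    d_max: float = 3.5,
    angle_min: float = 135.0,
    min_hbonds: int = 2,
) -> int:
    """NBP: residue pairs joined by >= min_hbonds base-base hydrogen bonds.

    Any partner counts, so overhang bases in contact with neighbors can
    raise NBP above the designed Watson-Crick count.
    """
    base = _base_mask(top)
    counts: dict[tuple[int, int], int] = {}
    for heavy, _h, acc in detect_hbonds(top, coords, d_max, angle_min):
        if not (base[heavy] and base[acc]):
            continue
        r1, r2 = int(top.resids[heavy]), int(top.resids[acc])
        key = (min(r1, r2), max(r1, r2))
        counts[key] = counts.get(key, 0) + 1
    return sum(1 for v in counts.values() if v >= min_hbonds)


def _ring_geometry(top: Topology, coords: np.ndarray):
    """Per-base ring centroid and unit normal (SVD plane fit)."""
    cents, norms, resids = [], [], []
    for rid in np.unique(top.resids):
        sel = np.flatnonzero(top.resids == rid)
        letter = base_letter(str(top.resnames[sel[0]]))
        ring = sel[np.isin(top.names[sel], BASE_RING_ATOMS[letter])]
        xyz = coords[ring]
        c = xyz.mean(axis=0)
        _u, _s, vt = np.linalg.svd(xyz - c)
        cents.append(c)
        norms.append(vt[2])
        resids.append(int(rid))
    return np.array(cents), np.array(norms), np.array(resids)


def count_base_stacks(
    top: Topology,
    coords: np.ndarray,
    d_max: float = 4.5,
    angle_max: float = 30.0,
) -> int:
    """NBS: base pairs with ring-centroid distance <= d_max and
    inter-ring-normal angle <= angle_max (normals are axial, so the
    angle is folded into [0, 90])."""
    cents, norms, _rid = _ring_geometry(top, coords)
    n = len(cents)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(cents[i] - cents[j]) > d_max:
                continue
            cosang = abs(float(np.dot(norms[i], norms[j])))
            ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
            if ang <= angle_max:
                count += 1
    return count


# ------------------------------------------------------------------------ SASA

def _sphere_lattice(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def sasa(
    top_or_radii: Topology | np.ndarray,
    coords: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Returns (total, per_atom) in Angstrom^2.  Radii come from the
    topology (vdW) or may be passed directly as an array.
    """
    radii = (
        top_or_radii.radii if isinstance(top_or_radii, Topology) else np.asarray(top_or_radii, float)
    )
    coords = np.asarray(coords, float)
    n = len(radii)
    R = radii + probe
    lattice = _sphere_lattice(n_points)
    areas = np.zeros(n)
    # neighbor lists via cutoff on expanded radii
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    cutoff2 = (R[:, None] + R[None, :]) ** 2
    for i in range(n):
        nbr = np.flatnonzero((d2[i] < cutoff2[i]) & (np.arange(n) != i))
        pts = coords[i] + R[i] * lattice
        if len(nbr):
            dist2 = np.sum((pts[:, None, :] - coords[nbr][None, :, :]) ** 2, axis=2)
            buried = np.any(dist2 < (R[nbr] ** 2)[None, :], axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = n_points
        areas[i] = 4.0 * np.pi * R[i] ** 2 * exposed / n_points
    return float(areas.sum()), areas


def region_sasa(
    top: Topology,
    per_atom: np.ndarray,
    role: str,
    positions: range | list[int],
) -> float:
    """Mean per-residue SASA (A^2) over the given strand positions."""
    vals = []
    for pos in positions:
        idx = top.atom_indices(role=role, position=pos)
        vals.append(per_atom[idx].sum())
    return float(np.mean(vals))


# ---------------------------------------------------------------------- volume

def volume_density(
    top: Topology,
    coords: np.ndarray,
    voxel: float = 0.5,
) -> tuple[float, float]:
    """Molecular volume (A^3) by vdW-sphere voxel union, and density (g/mL)."""
    radii = top.radii
    lo = (coords - radii[:, None]).min(axis=0) - voxel
    hi = (coords + radii[:, None]).max(axis=0) + voxel
    shape = np.ceil((hi - lo) / voxel).astype(int)
    occ = np.zeros(shape, dtype=bool)
    rmax = int(np.ceil(radii.max() / voxel)) + 1
    ax = np.arange(-rmax, rmax + 1)
    offs = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    for i in range(len(coords)):
        center_vox = np.floor((coords[i] - lo) / voxel).astype(int)
        cand = center_vox + offs
        centers = lo + (cand + 0.5) * voxel
        inside = np.sum((centers - coords[i]) ** 2, axis=1) <= radii[i] ** 2
        cand = cand[inside]
        ok = np.all((cand >= 0) & (cand < shape), axis=1)
        cand = cand[ok]
        occ[cand[:, 0], cand[:, 1], cand[:, 2]] = True
    V = float(occ.sum()) * voxel**3
    rho = top.masses.sum() / V * AMU_TO_G_PER_ML
    return V, rho


# -------------------------------------------------------------------- torsions

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang > -180.0 else 180.0)


_RING_ORDER = ["C1'", "C2'", "C3'", "C4'", "O4'"]
# endocyclic torsions nu0..nu4 as atom-name quadruples
_NU_ATOMS = [
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
]


def pseudorotation(top: Topology, coords: np.ndarray, role: str, position: int) -> tuple[float, float]:
    """Sugar pseudorotation phase P (deg, in [0, 360)) and amplitude.

    P follows tan(P) = ((nu4+nu1)-(nu3+nu0)) / (2 nu2 (sin36 + sin72)),
    quadrant-corrected via atan2.
    """
    sel = top.atom_indices(role=role, position=position)
    pos = {str(top.names[i]): coords[i] for i in sel if top.names[i] in set(sum(_NU_ATOMS, ()))}
    nus = [dihedral(pos[a], pos[b], pos[c], pos[d]) for a, b, c, d in _NU_ATOMS]
    num = (nus[4] + nus[1]) - (nus[3] + nus[0])
    den = 2.0 * nus[2] * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))
    P = np.degrees(np.arctan2(num, den))
    if P < 0:
        P += 360.0
    tau_m = abs(nus[2] / np.cos(np.radians(P)))
    return float(P), float(tau_m)


def classify_pucker(P: float, amplitude: float = 38.0) -> str:
    """Window classification: C3'-endo (North) for P in [-18, 54),
    C2'-endo (South) for P in [126, 198), otherwise 'other'.  Near-flat
    rings (amplitude < 5 deg) are 'other'."""
    if amplitude < 5.0:
        return "other"
    p = P % 360.0
    if p >= 342.0 or p < 54.0:
        return "C3'-endo"
    if 126.0 <= p < 198.0:
        return "C2'-endo"
    return "other"


def chi_dihedral(top: Topology, coords: np.ndarray, role: str, position: int) -> float:
    """Glycosidic torsion chi in degrees, (-180, 180].

    O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for pyrimidines.
    """
    sel = top.atom_indices(role=role, position=position)
    letter = base_letter(str(top.resnames[sel[0]]))
    wanted = ("O4'", "C1'", GLYCOSIDIC_N[letter], CHI_REF_ATOM[letter])
    pos = {}
    for i in sel:
        if top.names[i] in wanted:
            pos[str(top.names[i])] = coords[i]
    for name in wanted:
        if name not in pos:
            raise ValueError(f"missing atom {name!r} in {role} residue {position}")
    return dihedral(*(pos[n] for n in wanted))


def _dihedral_batch(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsions (deg) for stacked coordinate arrays (n, 3)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def pucker_series(ens: ConformationEnsemble, role: str, position: int) -> list[str]:
    """Pucker class of one residue for every frame (vectorized)."""
    top = ens.topology
    sel = top.atom_indices(role=role, position=position)
    idx = {}
    for i in sel:
        if top.names[i] in ("C1'", "C2'", "C3'", "C4'", "O4'"):
            idx[str(top.names[i])] = i
    X = ens.frames
    nus = np.stack(
        [
            _dihedral_batch(X[:, idx[a]], X[:, idx[b]], X[:, idx[c]], X[:, idx[d]])
            for a, b, c, d in _NU_ATOMS
        ]
    )
    num = (nus[4] + nus[1]) - (nus[3] + nus[0])
    den = 2.0 * nus[2] * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))
    P = np.degrees(np.arctan2(num, den)) % 360.0
    amp = np.abs(nus[2] / np.cos(np.radians(P)))
    return [classify_pucker(p, a) for p, a in zip(P, amp)]


def pucker_fractions(ens: ConformationEnsemble, role: str, position: int) -> dict[str, float]:
    """Fraction of frames per pucker class at one residue."""
    series = pucker_series(ens, role, position)
    counts = {"C3'-endo": 0, "C2'-endo": 0, "other": 0}
    for c in series:
        counts[c] += 1
    return {k: v / ens.n_frames for k, v in counts.items()}
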