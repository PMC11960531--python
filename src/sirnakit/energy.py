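"""Nonbonded interaction energies, positional decomposition, and
quasi-harmonic configurational entropy.

The guide-passenger interaction energy of a frame is decomposed as

    dE = dEel + dEvdW + dEsolv

with Coulomb electrostatics (k = 332.0636 kcal A / (mol e^2)),
Lennard-Jones 12-6 with Lorentz-Berthelot combination, and a solvation
term composed of a generalized-Born polar cross term (pairwise HCT
descreening radii computed on the complex, dielectric 78.5) plus a
nonpolar gamma*dSASA term (gamma = 0.0054 kcal/mol/A^2).  Because Born
radii are fixed at their complex-frame values, the polar term is
pairwise additive, and the positional decomposition over guide residues
sums exactly to the total.
"""

from __future__ import annotations

import warnings

import numpy as np

from .ensemble import ConformationEnsemble, Topology
from .geometry import detect_hbonds, kabsch_rotation, pucker_series, sasa

__all__ = [
    "born_radii",
    "interaction_energy",
    "positional_energy",
    "conditional_energies",
    "entropy_quasiharmonic",
    "duplex_entropy",
]

COULOMB_K = 332.0636  # kcal A / (mol e^2)
EPS_SOLVENT = 78.5
GB_OFFSET = 0.09  # A, intrinsic radius offset
GAMMA_NONPOLAR = 0.0054  # kcal / (mol A^2)
#: HCT descreening scale factors by element
HCT_SCALE = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "F": 0.88, "P": 0.86}

KB_J = 1.380649e-23
HBAR_J = 1.054571817e-34
AMU_KG = 1.66053906660e-27
R_CAL = 1.98720425864083  # cal / (mol K)


def born_radii(top: Topology, coords: np.ndarray, subset: np.ndarray | None = None) -> np.ndarray:
    """Effective Born radii by pairwise HCT descreening (A).

    ``subset`` restricts the system to the given atom indices (radii of
    and due to those atoms only).
    """
    idx = np.arange(top.n_atoms) if subset is None else np.asarray(subset)
    xyz = coords[idx]
    rho = np.array([top.radii[i] for i in idx]) - GB_OFFSET
    scale = np.array([HCT_SCALE[str(top.elements[i])] for i in idx])
    n = len(idx)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    if n > 1 and np.min(d[np.triu_indices(n, 1)]) < 1e-6:
        raise ValueError("zero interatomic distance")
    rs = scale * rho  # descreening radius of each "other" atom
    inv_rho = 1.0 / rho
    integral = np.zeros((n, n))
    for j in range(n):
        r = d[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            L = np.maximum(rho, np.abs(r - rs[j]))
            U = r + rs[j]
            term = 0.5 * (
                1.0 / L
                - 1.0 / U
                + 0.5 / r * np.log(L / U)
                + 0.25 * (r - rs[j] ** 2 / r) * (1.0 / U**2 - 1.0 / L**2)
            )
        term[np.arange(n) == j] = 0.0
        # atom fully engulfing the descreening sphere contributes nothing
        term[rho >= r + rs[j]] = 0.0
        integral[:, j] = term
    inv_R = inv_rho - integral.sum(axis=1)
    inv_R = np.maximum(inv_R, 1.0 / 30.0)  # guard against over-descreening
    return 1.0 / inv_R


def _pair_matrices(top: Topology, coords: np.ndarray, A: np.ndarray, B: np.ndarray, R: np.ndarray | None):
    xyzA, xyzB = coords[A], coords[B]
    d = np.linalg.norm(xyzA[:, None, :] - xyzB[None, :, :], axis=2)
    if d.min() < 1e-6:
        raise ValueError("zero interatomic distance between groups")
    qA, qB = top.charges[A], top.charges[B]
    eel = COULOMB_K * np.outer(qA, qB) / d
    sig = 0.5 * (top.sigma[A][:, None] + top.sigma[B][None, :])
    eps = np.sqrt(np.outer(top.epsilon[A], top.epsilon[B]))
    sr6 = (sig / d) ** 6
    evdw = 4.0 * eps * (sr6**2 - sr6)
    if R is not None:
        RA = R[A][:, None]
        RB = R[B][None, :]
        fgb = np.sqrt(d**2 + RA * RB * np.exp(-(d**2) / (4.0 * RA * RB)))
        egb = -COULOMB_K * (1.0 - 1.0 / EPS_SOLVENT) * np.outer(qA, qB) / fgb
    else:
        egb = np.zeros_like(d)
    return eel, evdw, egb


def interaction_energy(
    top: Topology,
    coords: np.ndarray,
    group_A: np.ndarray,
    group_B: np.ndarray,
    probe: float = 1.4,
    include_solv: bool = True,
) -> dict[str, float]:
    """Cross-group nonbonded energy components (kcal/mol) for one frame.

    Returns dEel, dEvdW, dEsolv and their sum dE.  Groups must be
    disjoint index arrays.
    """
    A = np.asarray(group_A, dtype=int)
    B = np.asarray(group_B, dtype=int)
    if np.intersect1d(A, B).size:
        raise ValueError("groups must be disjoint")
    both = np.concatenate([A, B])
    if include_solv:
        R_local = born_radii(top, coords, subset=both)
        R = np.full(top.n_atoms, np.nan)
        R[both] = R_local
    else:
        R = None
    eel, evdw, egb = _pair_matrices(top, coords, A, B, R)
    dEel = float(eel.sum())
    dEvdW = float(evdw.sum())
    if include_solv:
        _t, per_ab = sasa(top.radii[both], coords[both], probe)
        _t, per_a = sasa(top.radii[A], coords[A], probe)
        _t, per_b = sasa(top.radii[B], coords[B], probe)
        dsasa = per_ab.sum() - per_a.sum() - per_b.sum()
        dEsolv = float(egb.sum()) + GAMMA_NONPOLAR * float(dsasa)
    else:
        dEsolv = 0.0
    return {
        "dEel": dEel,
        "dEvdW": dEvdW,
        "dEsolv": dEsolv,
        "dE": dEel + dEvdW + dEsolv,
    }


def positional_energy(
    ens: ConformationEnsemble,
    probe: float = 1.4,
    include_solv: bool = True,
    hbond_kwargs: dict | None = None,
) -> dict[str, np.ndarray]:
    """Frame-averaged per-guide-position energies dE_i and H-bond counts.

    dE_i is the interaction energy of guide residue i with the entire
    passenger strand; the decomposition is exact: sum_i dE_i equals the
    total guide-passenger dE of the same frames.  The nonpolar dSASA
    term is attributed per atom (guide atoms to their own residue,
    passenger atoms to the nearest guide residue).  Nhb_i counts
    inter-strand hydrogen bonds involving guide residue i.
    """
    top = ens.topology
    G = top.atom_indices(role="guide")
    P = top.atom_indices(role="passenger")
    g_positions = sorted({int(p) for p in top.positions[G]})
    n_pos = len(g_positions)
    de_i = np.zeros(n_pos)
    de_el = np.zeros(n_pos)
    de_vdw = np.zeros(n_pos)
    de_solv = np.zeros(n_pos)
    nhb_i = np.zeros(n_pos)
    hbond_kwargs = hbond_kwargs or {}
    guide_pos_of = {int(p): k for k, p in enumerate(g_positions)}
    for f in range(ens.n_frames):
        xyz = ens.frames[f]
        if include_solv:
            both = np.concatenate([G, P])
            R_local = born_radii(top, xyz, subset=both)
            R = np.full(top.n_atoms, np.nan)
            R[both] = R_local
        else:
            R = None
        eel, evdw, egb = _pair_matrices(top, xyz, G, P, R)
        rowpos = top.positions[G]
        for pos in g_positions:
            rows = rowpos == pos
            k = guide_pos_of[pos]
            de_el[k] += eel[rows].sum()
            de_vdw[k] += evdw[rows].sum()
            de_solv[k] += egb[rows].sum()
        if include_solv:
            both = np.concatenate([G, P])
            _t, per_ab = sasa(top.radii[both], xyz[both], probe)
            _t, per_g = sasa(top.radii[G], xyz[G], probe)
            _t, per_p = sasa(top.radii[P], xyz[P], probe)
            darea_g = per_ab[: len(G)] - per_g
            darea_p = per_ab[len(G):] - per_p
            # passenger atoms attribute their area change to the
            # nearest guide residue so the decomposition stays exact
            dmat = np.linalg.norm(xyz[P][:, None, :] - xyz[G][None, :, :], axis=2)
            nearest_guide = np.argmin(dmat, axis=1)
            for pos in g_positions:
                k = guide_pos_of[pos]
                rows = rowpos == pos
                npl = GAMMA_NONPOLAR * darea_g[rows].sum()
                npl += GAMMA_NONPOLAR * darea_p[rows[nearest_guide]].sum()
                de_solv[k] += npl
        for heavy, _h, acc in detect_hbonds(top, xyz, **hbond_kwargs):
            r1, r2 = str(top.roles[heavy]), str(top.roles[acc])
            if r1 == r2:
                continue
            gpos = int(top.positions[heavy if r1 == "guide" else acc])
            nhb_i[guide_pos_of[gpos]] += 1
    nf = ens.n_frames
    de_el /= nf
    de_vdw /= nf
    de_solv /= nf
    de_i = de_el + de_vdw + de_solv
    return {
        "positions": np.array(g_positions),
        "dE_i": de_i,
        "dEel_i": de_el,
        "dEvdW_i": de_vdw,
        "dEsolv_i": de_solv,
        "Nhb_i": nhb_i / nf,
    }


def conditional_energies(
    ens: ConformationEnsemble,
    role: str,
    position: int,
    energies: np.ndarray | None = None,
    include_solv: bool = False,
) -> dict[str, float | None]:
    """Pucker-class-conditional residue interaction energies.

    Frames are grouped by the residue's sugar pucker class; the result
    holds class-conditional means dE_C2endo / dE_C3endo and their
    difference ddE (C2'-endo minus C3'-endo).  A class with no frames is
    reported as None (absent, never imputed).  ``energies`` may supply a
    precomputed per-frame energy series; otherwise the residue's
    cross-strand interaction energy is computed per frame.
    """
    top = ens.topology
    if energies is None:
        other = "passenger" if role == "guide" else "guide"
        A = top.atom_indices(role=role, position=position)
        B = top.atom_indices(role=other)
        energies = np.array(
            [
                interaction_energy(top, ens.frames[f], A, B, include_solv=include_solv)["dE"]
                for f in range(ens.n_frames)
            ]
        )
    energies = np.asarray(energies, dtype=float)
    if len(energies) != ens.n_frames:
        raise ValueError("energies must have one value per frame")
    classes = np.array(pucker_series(ens, role, position))
    out: dict[str, float | None] = {}
    means = {}
    for label, key in (("C2'-endo", "dE_C2endo"), ("C3'-endo", "dE_C3endo")):
        sel = classes == label
        means[key] = float(energies[sel].mean()) if sel.any() else None
        out[key] = means[key]
        out[key.replace("dE", "n")] = int(sel.sum())
    if means["dE_C2endo"] is None or means["dE_C3endo"] is None:
        out["ddE"] = None
    else:
        out["ddE"] = means["dE_C2endo"] - means["dE_C3endo"]
    return out


def _entropy_from_covariance(cov: np.ndarray, T: float) -> float:
    """Quasi-harmonic entropy (cal/mol/K) from a mass-weighted coordinate
    covariance matrix in amu*A^2."""
    lam = np.linalg.eigvalsh(cov)
    lam = lam[lam > 1e-10]  # drop zero/negative modes
    if lam.size == 0:
        return 0.0
    lam_si = lam * AMU_KG * 1e-20  # kg m^2
    omega = np.sqrt(KB_J * T / lam_si)
    x = HBAR_J * omega / (KB_J * T)
    s = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return float(R_CAL * s.sum())


def entropy_quasiharmonic(
    ens: ConformationEnsemble,
    T: float = 300.0,
    subset: np.ndarray | None = None,
    align: bool = True,
) -> float:
    """T*S (kcal/mol) from the quasi-harmonic model.

    The mass-weighted covariance of atomic fluctuations is
    diagonalized; each mode contributes the quantum harmonic-oscillator
    entropy at temperature T.  With ``align`` (default) frames are
    first superimposed on the first frame to remove global
    rotation/translation.  Fewer than 3N+1 frames triggers a warning
    and a reduced-rank treatment (zero modes are dropped).
    """
    top = ens.topology
    idx = np.arange(top.n_atoms) if subset is None else np.asarray(subset)
    n_dof = 3 * len(idx)
    if ens.n_frames < n_dof + 1:
        warnings.warn(
            f"{ens.n_frames} frames < 3N+1 = {n_dof + 1}: covariance is "
            "rank-deficient; zero modes are dropped",
            stacklevel=2,
        )
    X = ens.frames[:, idx, :].copy()
    if align and len(idx) >= 3 and ens.n_frames > 1:
        ref = X[0]
        for f in range(ens.n_frames):
            Rm, cp, cq = kabsch_rotation(X[f], ref)
            X[f] = (X[f] - cp) @ Rm.T + cq
    m = np.sqrt(top.masses[idx])
    Xw = (X * m[None, :, None]).reshape(ens.n_frames, -1)
    mean = Xw.mean(axis=0)
    dev = Xw - mean
    cov = dev.T @ dev / max(ens.n_frames - 1, 1)
    S = _entropy_from_covariance(cov, T)
    return T * S / 1000.0  # kcal/mol


def duplex_entropy(ens: ConformationEnsemble, T: float = 300.0) -> float:
    """Duplex-formation TdS = T(S_complex - S_guide - S_passenger), kcal/mol."""
    top = ens.topology
    G = top.atom_indices(role="guide")
    P = top.atom_indices(role="passenger")
    ts_c = entropy_quasiharmonic(ens, T)
    ts_g = entropy_quasiharmonic(ens, T, subset=G)
    ts_p = entropy_quasiharmonic(ens, T, subset=P)
    return ts_c - ts_g - ts_p
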