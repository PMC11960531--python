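"""Geometric features against independent oracles: quaternion RMSD,
numerical surface integration, analytic spheres, torsion math."""

import numpy as np
import pytest

from conftest import make_topology
from sirnakit import geometry as geo


# ------------------------------------------------------------ RMSD oracles

def quaternion_rmsd(P, Q):
    """Independent superposition via the quaternion eigenvalue method."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e2 = (np.sum(P**2) + np.sum(Q**2) - 2.0 * lam) / len(P)
    return np.sqrt(max(e2, 0.0))


class TestKabsch:
    def test_self_is_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        assert geo.kabsch_rmsd(X, X) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_is_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        R, _c, _c2 = geo.kabsch_rotation(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        moved = X @ R.T + np.array([5.0, -3.0, 11.0])
        assert geo.kabsch_rmsd(moved, X) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(10, 3))
        Q = P + rng.normal(scale=0.3, size=(10, 3))
        assert geo.kabsch_rmsd(P, Q) == pytest.approx(quaternion_rmsd(P, Q), abs=1e-9)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            geo.kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


# ------------------------------------------------------------- end to end

class TestEndToEnd:
    def test_matches_helix_constant_oracle(self, built_parent):
        """Pair centers of mass sit on a helix: the end-to-end distance
        follows from rise/twist constants and the first pair's offset."""
        from sirnakit.structure import RISE, TWIST

        top, xyz = built_parent.topology, built_parent.coords

        def pair_com(gpos, ppos):
            idx = np.concatenate(
                [
                    geo._base_atom_indices(top, "guide", gpos),
                    geo._base_atom_indices(top, "passenger", ppos),
                ]
            )
            m = top.masses[idx]
            return (xyz[idx] * m[:, None]).sum(axis=0) / m.sum()

        com1 = pair_com(1, 19)
        r = np.hypot(com1[0], com1[1])
        dtheta = np.radians(18 * TWIST)
        chord = 2.0 * r * abs(np.sin(dtheta / 2.0))
        expected = np.hypot(18 * RISE, chord)
        got = geo.end_to_end(top, xyz)
        assert got == pytest.approx(expected, abs=0.2)

    def test_translation_invariance(self, built_parent):
        top, xyz = built_parent.topology, built_parent.coords
        x0 = geo.end_to_end(top, xyz)
        x1 = geo.end_to_end(top, xyz + np.array([10.0, -5.0, 3.0]))
        assert x1 == pytest.approx(x0, abs=1e-9)

    def test_noise_changes_per_frame_value(self, built_parent):
        from sirnakit.ensemble import SynthSpec
        from sirnakit.structure import synthesize_ensemble

        ens = synthesize_ensemble(
            built_parent, SynthSpec(0.0, 0.3, 0.0, n_frames=2, seed=5)
        )
        x = [geo.end_to_end(ens.topology, ens.frames[f]) for f in range(2)]
        assert x[0] != x[1]


# ---------------------------------------------------------- hydrogen bonds

class TestHBonds:
    def test_wc_pair_counts(self, built_parent, pairs):
        """Built G:C pairs carry 3 base-pairing H-bonds, A:U pairs 2."""
        top, xyz = built_parent.topology, built_parent.coords
        counts = {}
        for heavy, _h, acc in geo.detect_hbonds(top, xyz):
            r1, r2 = int(top.resids[heavy]), int(top.resids[acc])
            key = (min(r1, r2), max(r1, r2))
            counts[key] = counts.get(key, 0) + 1
        seq = pairs[0].parent.guide.sequence
        for i in range(1, 20):
            expected = 3 if seq[i - 1] in "GC" else 2
            assert counts[(i - 1, 40 - i)] == expected, f"pair {i}"

    def test_distant_atoms_none(self):
        top = make_topology(["N1", "H1", "O1"], ["N", "H", "O"], resids=[0, 0, 1])
        xyz = np.array([[0, 0, 0], [1.0, 0, 0], [11.0, 0, 0.0]])
        assert geo.detect_hbonds(top, xyz) == []

    def test_boundary_angle_counts(self):
        """A donor-H...acceptor angle of exactly 135 deg is included."""
        top = make_topology(["N1", "H1", "O1"], ["N", "H", "O"], resids=[0, 0, 1])
        h = np.array([0.0, 0.0, 0.0])
        donor = np.array([-1.0, 0.0, 0.0])
        ang = np.radians(135.0)
        acceptor = h + 2.0 * np.array([-np.cos(ang), np.sin(ang), 0.0])
        hb = geo.detect_hbonds(top, np.stack([donor, h, acceptor]))
        assert len(hb) == 1


class TestCounts:
    def test_ideal_build_nbp(self, built_parent):
        assert geo.count_base_pairs(built_parent.topology, built_parent.coords) == 19

    def test_fully_frayed_nbp(self, built_parent):
        from sirnakit.ensemble import SynthSpec
        from sirnakit.structure import synthesize_ensemble

        ens = synthesize_ensemble(
            built_parent, SynthSpec(0.0, 0.0, 1.0, n_frames=1, seed=0)
        )
        assert geo.count_base_pairs(ens.topology, ens.frames[0]) == 17

    def test_stack_count_regression(self, built_parent):
        """Ideal A-form build: every sequential base step stacks (20 per
        21-mer strand including the overhangs); pinned regression value."""
        assert geo.count_base_stacks(built_parent.topology, built_parent.coords) == 40


# ------------------------------------------------------------------- SASA

def latlong_sasa(coords, radii, probe=1.4, n_theta=180, n_phi=360):
    """Independent numerical surface integration on a lat-long quadrature."""
    total = 0.0
    per = []
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    T, Ph = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack(
        [np.sin(T) * np.cos(Ph), np.sin(T) * np.sin(Ph), np.cos(T)], axis=-1
    )
    w = np.sin(T) * (np.pi / n_theta) * (2 * np.pi / n_phi)
    R = np.asarray(radii) + probe
    for i in range(len(coords)):
        pts = coords[i] + R[i] * dirs.reshape(-1, 3)
        exposed = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            exposed &= np.sum((pts - coords[j]) ** 2, axis=1) >= R[j] ** 2
        area = R[i] ** 2 * (w.reshape(-1) * exposed).sum()
        per.append(area)
        total += area
    return total, np.array(per)


class TestSasa:
    def test_single_sphere_analytic(self):
        total, per = geo.sasa(np.array([1.7]), np.zeros((1, 3)))
        assert total == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-9)

    def test_far_apart_additive(self):
        radii = np.array([1.5, 1.2])
        xyz = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        total, per = geo.sasa(radii, xyz)
        iso = sum(4 * np.pi * (r + 1.4) ** 2 for r in radii)
        assert total == pytest.approx(iso, rel=1e-9)

    def test_two_overlapping_spheres_vs_integration(self):
        radii = np.array([1.7, 1.52])
        xyz = np.array([[0.0, 0, 0], [2.0, 0.5, -0.3]])
        ours, _p = geo.sasa(radii, xyz)
        oracle, _p2 = latlong_sasa(xyz, radii)
        assert ours == pytest.approx(oracle, rel=0.01)

    @pytest.mark.parametrize("seed", range(0, 100, 4))
    def test_random_clusters_vs_integration(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        xyz = rng.uniform(-2, 2, size=(n, 3))
        radii = rng.uniform(1.2, 1.9, size=n)
        ours, _p = geo.sasa(radii, xyz)
        oracle, _p2 = latlong_sasa(xyz, radii)
        assert ours == pytest.approx(oracle, rel=0.01)

    def test_rotation_invariance(self, built_parent):
        top, xyz = built_parent.topology, built_parent.coords
        R, _a, _b = geo.kabsch_rotation(
            np.random.default_rng(3).normal(size=(4, 3)),
            np.random.default_rng(4).normal(size=(4, 3)),
        )
        t1, _ = geo.sasa(top, xyz)
        t2, _ = geo.sasa(top, xyz @ R.T + 7.0)
        # invariant up to the finite sphere lattice resolution
        assert t2 == pytest.approx(t1, rel=5e-3)


class TestVolume:
    def test_single_sphere(self):
        top = make_topology(["C1"], ["C"], radii=[1.7], masses=[12.011])
        V, rho = geo.volume_density(top, np.zeros((1, 3)))
        assert V == pytest.approx(4.0 / 3.0 * np.pi * 1.7**3, rel=0.02)

    def test_grid_convergence(self):
        rng = np.random.default_rng(2)
        n = 20
        top = make_topology(
            [f"C{i}" for i in range(n)], ["C"] * n, radii=[1.7] * n, masses=[12.011] * n
        )
        xyz = rng.uniform(-4, 4, size=(n, 3))
        v1, _ = geo.volume_density(top, xyz, voxel=0.5)
        v2, _ = geo.volume_density(top, xyz, voxel=0.25)
        assert abs(v2 - v1) / v2 < 0.01

    def test_density_units(self):
        # one carbon in 1 A^3-scale sphere: rho = m/V * 1.66054
        top = make_topology(["C1"], ["C"], radii=[1.7], masses=[12.011])
        V, rho = geo.volume_density(top, np.zeros((1, 3)))
        assert rho == pytest.approx(12.011 / V * 1.66054, rel=1e-9)


# --------------------------------------------------------------- torsions

class TestTorsions:
    def test_constructed_60_degrees(self):
        p0 = np.array([1.0, 0.0, 1.0])
        p1 = np.array([0.0, 0.0, 1.0])
        p2 = np.array([0.0, 0.0, 0.0])
        ang = np.radians(60.0)
        p3 = np.array([np.cos(ang), np.sin(ang), -1.0])
        # IUPAC sign: looking from p1 toward p2, p3 appears rotated
        # clockwise from p0 by 60 deg -> +60
        assert geo.dihedral(p0, p1, p2, p3) == pytest.approx(60.0, abs=1e-9)

    def test_rotation_invariance_chi(self, built_parent):
        top, xyz = built_parent.topology, built_parent.coords
        chi0 = geo.chi_dihedral(top, xyz, "guide", 3)
        R, _a, _b = geo.kabsch_rotation(
            np.random.default_rng(8).normal(size=(5, 3)),
            np.random.default_rng(9).normal(size=(5, 3)),
        )
        chi1 = geo.chi_dihedral(top, xyz @ R.T - 4.0, "guide", 3)
        assert chi1 == pytest.approx(chi0, abs=1e-6)

    def test_built_chi_in_anti_range(self, built_parent):
        for pos in (1, 5, 10):
            chi = geo.chi_dihedral(built_parent.topology, built_parent.coords, "guide", pos)
            assert -180.0 < chi < -90.0

    def test_missing_atom_named(self, built_parent):
        from sirnakit.ensemble import Topology

        top = built_parent.topology
        keep = np.flatnonzero(
            ~((top.roles == "guide") & (top.positions == 1) & (top.names == "O4'"))
        )
        sub = Topology(
            names=top.names[keep],
            elements=top.elements[keep],
            resids=top.resids[keep],
            resnames=top.resnames[keep],
            roles=top.roles[keep],
            positions=top.positions[keep],
            charges=top.charges[keep],
            sigma=top.sigma[keep],
            epsilon=top.epsilon[keep],
            masses=top.masses[keep],
            radii=top.radii[keep],
        )
        with pytest.raises(ValueError, match="O4'"):
            geo.chi_dihedral(sub, built_parent.coords[keep], "guide", 1)


class TestPseudorotation:
    def _independent_P(self, top, xyz, role, pos):
        """Recompute P with an independent torsion implementation."""

        def torsion(a, b, c, d):
            # atan2 form with the IUPAC sign (clockwise viewed b->c positive)
            b1, b2, b3 = b - a, c - b, d - c
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            x = np.dot(n1, n2) * np.linalg.norm(b2)
            y = -np.dot(np.cross(n1, n2), b2)
            return np.degrees(np.arctan2(y, x))

        sel = top.atom_indices(role=role, position=pos)
        at = {str(top.names[i]): xyz[i] for i in sel}
        quads = [
            ("C4'", "O4'", "C1'", "C2'"),
            ("O4'", "C1'", "C2'", "C3'"),
            ("C1'", "C2'", "C3'", "C4'"),
            ("C2'", "C3'", "C4'", "O4'"),
            ("C3'", "C4'", "O4'", "C1'"),
        ]
        nus = [torsion(at[a], at[b], at[c], at[d]) for a, b, c, d in quads]
        num = (nus[4] + nus[1]) - (nus[3] + nus[0])
        den = 2 * nus[2] * (np.sin(np.radians(36)) + np.sin(np.radians(72)))
        P = np.degrees(np.arctan2(num, den))
        return P % 360.0

    def test_north_build_classifies_c3_endo(self, built_parent):
        top, xyz = built_parent.topology, built_parent.coords
        for pos in (2, 7, 15):
            P, amp = geo.pseudorotation(top, xyz, "guide", pos)
            assert geo.classify_pucker(P, amp) == "C3'-endo"
            assert P == pytest.approx(self._independent_P(top, xyz, "guide", pos), abs=1e-6)

    def test_south_build_classifies_c2_endo(self, pairs):
        from sirnakit.structure import build_duplex

        state = {("guide", 5): "C2'-endo"}
        b = build_duplex(pairs[0].parent, pucker_state=state)
        P, amp = geo.pseudorotation(b.topology, b.coords, "guide", 5)
        assert geo.classify_pucker(P, amp) == "C2'-endo"
        assert P == pytest.approx(162.0, abs=3.0)

    def test_classification_windows(self):
        assert geo.classify_pucker(18.0) == "C3'-endo"
        assert geo.classify_pucker(-17.0 % 360) == "C3'-endo"
        assert geo.classify_pucker(162.0) == "C2'-endo"
        assert geo.classify_pucker(90.0) == "other"
        assert geo.classify_pucker(18.0, amplitude=2.0) == "other"
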