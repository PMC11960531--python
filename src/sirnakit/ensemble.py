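"""In-memory containers for duplex topologies and conformational ensembles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Topology", "AtomRecord", "ConformationEnsemble", "SynthSpec"]


@dataclass(frozen=True)
class AtomRecord:
    """Single-atom view: identity plus nonbonded parameters."""

    name: str
    element: str
    residue_index: int
    residue_name: str
    strand_role: str  # "guide" | "passenger"
    residue_position: int  # 1-based within its strand
    partial_charge: float  # e
    lj_sigma: float  # Angstrom
    lj_epsilon: float  # kcal/mol
    mass: float  # amu
    radius: float  # vdW radius, Angstrom


@dataclass
class Topology:
    """Column-oriented atom table shared by all frames of an ensemble."""

    names: np.ndarray  # str
    elements: np.ndarray  # str
    resids: np.ndarray  # int, 0-based running residue index
    resnames: np.ndarray  # str
    roles: np.ndarray  # "guide" | "passenger"
    positions: np.ndarray  # int, 1-based residue position within strand
    charges: np.ndarray  # float, e
    sigma: np.ndarray  # float, Angstrom
    epsilon: np.ndarray  # float, kcal/mol
    masses: np.ndarray  # float, amu
    radii: np.ndarray  # float, Angstrom

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom_indices(self, role: str | None = None, position: int | None = None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if role is not None:
            mask &= self.roles == role
        if position is not None:
            mask &= self.positions == position
        return np.flatnonzero(mask)

    def residue_keys(self) -> list[tuple[str, int]]:
        seen: list[tuple[str, int]] = []
        for rid in np.unique(self.resids):
            i = int(np.flatnonzero(self.resids == rid)[0])
            seen.append((str(self.roles[i]), int(self.positions[i])))
        return seen


@dataclass
class ConformationEnsemble:
    """Atoms plus one or more coordinate frames of a duplex.

    ``frames`` has shape (n_frames, n_atoms, 3) in Angstrom.  Frames are
    statistically independent conformations; ``frame_interval`` is an
    arbitrary unit spacing kept only for bookkeeping.
    """

    topology: Topology
    frames: np.ndarray
    provenance: str = "built"  # "built" | "synthetic" | "file"
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"{self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def atom_records(self) -> list[AtomRecord]:
        t = self.topology
        return [
            AtomRecord(
                name=str(t.names[i]),
                element=str(t.elements[i]),
                residue_index=int(t.resids[i]),
                residue_name=str(t.resnames[i]),
                strand_role=str(t.roles[i]),
                residue_position=int(t.positions[i]),
                partial_charge=float(t.charges[i]),
                lj_sigma=float(t.sigma[i]),
                lj_epsilon=float(t.epsilon[i]),
                mass=float(t.masses[i]),
                radius=float(t.radii[i]),
            )
            for i in range(t.n_atoms)
        ]


@dataclass
class SynthSpec:
    """Controls for the synthetic ensemble generator.

    pucker_occupancy: target C2'-endo fraction per residue, either a
    scalar applied to every residue or a mapping {(role, position):
    fraction}; residues not listed stay C3'-endo.
    positional_noise_sigma: isotropic Gaussian displacement (Angstrom)
    added to every atom per frame.
    fray_prob: per-frame probability that each terminal core base pair
    is open (its guide-side base displaced beyond hydrogen-bond range).
    """

    pucker_occupancy: float | dict[tuple[str, int], float] = 0.0
    positional_noise_sigma: float = 0.1
    fray_prob: float = 0.0
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        occ = self.pucker_occupancy
        vals = [occ] if isinstance(occ, (int, float)) else list(occ.values())
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("pucker occupancies must lie in [0, 1]")
        if not 0.0 <= self.fray_prob <= 1.0:
            raise ValueError("fray_prob must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.positional_noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    def occupancy_for(self, role: str, position: int) -> float:
        if isinstance(self.pucker_occupancy, (int, float)):
            return float(self.pucker_occupancy)
        return float(self.pucker_occupancy.get((role, position), 0.0))
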