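"""Empirical nearest-neighbor (NN) duplex thermodynamics.

Duplex formation enthalpy/entropy is modelled as the sum of dinucleotide
stack increments over the 19-bp core, plus a helix-initiation term and a
penalty for each terminal A:U core pair.  Free energy at 37 C follows
dG37 = dH - 310.15*dS/1000 and the two-state melting temperature of a
non-self-complementary duplex is

    Tm(K) = dH*1000 / (dS + R ln(CT/4)),   CT = total strand conc. (M).

The packaged increments are the published Watson-Crick RNA parameters at
the 1 M NaCl reference.  Chemically modified duplexes are scored with
the unmodified increments: the NN model has no 2'-OMe/2'-F terms, so its
predictions are most faithful for parent sequences.

The positional decomposition dE_i assigns to base-pair position i the
enthalpy of the stacks that flank it -- either their mean
(``flank-average``, the default) or their sum (``flank-sum``).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .dataset import DuplexRecord, ModifiedStrand, align_duplex

__all__ = [
    "NNParameterSet",
    "ThermoResult",
    "load_nn_parameters",
    "duplex_thermo",
    "predict_tm",
    "positional_dE",
    "stack_tm_features",
]

NN_PARAMS_SHA256 = "9f014a8018f1ac28c2c3f3f1e9cf8c83e846d51e37cb71f161a3118e30b601ea"

R_GAS = 1.98720425864083  # cal / (mol K)
T37_K = 310.15
#: experimental melting condition: 2 uM duplex -> 4 uM total strands
DEFAULT_CT_M = 4e-6

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(dinuc: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(dinuc))


@dataclass(frozen=True)
class NNParameterSet:
    """Stack increments (dH kcal/mol, dS cal/mol.K) plus end terms."""

    stack_increments: dict[str, tuple[float, float]]
    init_term: tuple[float, float]
    terminal_AU_penalty: tuple[float, float]

    def stack(self, dinuc: str) -> tuple[float, float]:
        """Resolve a 5'->3' WC dinucleotide stack, using rc symmetry."""
        if dinuc in self.stack_increments:
            return self.stack_increments[dinuc]
        rc = _revcomp(dinuc)
        if rc in self.stack_increments:
            return self.stack_increments[rc]
        raise KeyError(f"no NN increment for stack {dinuc!r}")

    def dG37(self, dinuc: str) -> float:
        dh, ds = self.stack(dinuc)
        return dh - T37_K * ds / 1000.0


@dataclass(frozen=True)
class ThermoResult:
    duplex_id: str
    dH: float  # kcal/mol
    dS: float  # cal/(mol K)
    dG37: float  # kcal/mol
    tm_pred: float  # degrees C
    positional_dE: np.ndarray  # kcal/mol, index 0 = position 1..19
    positional_convention: str
    stack_tm: dict[str, float]  # per-stack Tm-like feature, key "g<i>g<i+1>:<XY>"


def load_nn_parameters(path: str | Path | None = None, check: bool = True) -> NNParameterSet:
    """Load stack increments from the packaged (or a user) parameter table."""
    if path is None:
        data = resources.files("sirnakit").joinpath("data/nn_rna_wc.tsv").read_bytes()
        if check and hashlib.sha256(data).hexdigest() != NN_PARAMS_SHA256:
            raise IOError("NN parameter table failed its checksum")
    else:
        data = Path(path).read_bytes()
    stacks: dict[str, tuple[float, float]] = {}
    init = term_au = None
    for line in data.decode().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("stack\t"):
            continue
        key, dh, ds = line.split("\t")
        val = (float(dh), float(ds))
        if key == "init":
            init = val
        elif key == "terminal_AU":
            term_au = val
        else:
            stacks[key] = val
    if init is None or term_au is None:
        raise ValueError("parameter table lacks init and/or terminal_AU rows")
    return NNParameterSet(stacks, init, term_au)


_DEFAULT_PARAMS: NNParameterSet | None = None


def default_parameters() -> NNParameterSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_nn_parameters()
    return _DEFAULT_PARAMS


def _core(strand: ModifiedStrand) -> str:
    """19-nt paired core (overhang dTdT excluded)."""
    return strand.sequence[:19]


def _validated_core(duplex: DuplexRecord) -> str:
    aln = align_duplex(duplex.guide, duplex.passenger)
    if not aln.valid:
        raise ValueError(
            f"{duplex.duplex_id}: NN increments undefined for non-WC pairs "
            f"{aln.mismatches}"
        )
    return _core(duplex.guide)


def predict_tm(
    dH: float,
    dS: float,
    strand_conc: float = DEFAULT_CT_M,
    salt: float | None = None,
    n_phosphates: int | None = None,
) -> float:
    """Two-state melting temperature in degrees C.

    ``strand_conc`` is the total strand concentration CT (M) for a
    non-self-complementary duplex.  When ``salt`` (monovalent, M) and
    ``n_phosphates`` are given, dS is first shifted by the standard
    phosphate-count entropy correction 0.368 * N * ln[Na+]; otherwise
    values are reported at the 1 M reference.
    """
    if dH >= 0 or dS >= 0:
        raise ValueError("no melting transition: dH and dS must be negative")
    ds = dS
    if salt is not None:
        if n_phosphates is None:
            raise ValueError("salt correction requires n_phosphates")
        ds = dS + 0.368 * n_phosphates * math.log(salt)
    tm_K = dH * 1000.0 / (ds + R_GAS * math.log(strand_conc / 4.0))
    return tm_K - 273.15


def positional_dE(
    core: str, params: NNParameterSet | None = None, convention: str = "flank-average"
) -> np.ndarray:
    """Per-position stack enthalpy dE_i (kcal/mol) for i = 1..len(core).

    Position i is flanked by the stack to its 5' side (absent at i=1)
    and the stack to its 3' side (absent at the last position).  The
    default assigns each position the mean of its flanking stack dH
    increments; ``flank-sum`` assigns the sum.
    """
    if convention not in ("flank-average", "flank-sum"):
        raise ValueError(f"unknown convention {convention!r}")
    params = params or default_parameters()
    n = len(core)
    stack_dh = np.array([params.stack(core[i : i + 2])[0] for i in range(n - 1)])
    de = np.zeros(n)
    for i in range(n):
        flanks = []
        if i > 0:
            flanks.append(stack_dh[i - 1])
        if i < n - 1:
            flanks.append(stack_dh[i])
        de[i] = np.mean(flanks) if convention == "flank-average" else np.sum(flanks)
    return de


def stack_tm_features(
    core: str,
    params: NNParameterSet | None = None,
    strand_conc: float = DEFAULT_CT_M,
) -> dict[str, float]:
    """Tm-like ranking feature per core dinucleotide stack.

    Each stack's dH/dS increment plus the initiation term is pushed
    through the two-state Tm relation.  Individual stacks do not melt
    two-state, so the value is a relative stability feature, not a
    melting prediction; GC-rich stacks rank above AU-rich ones.
    """
    params = params or default_parameters()
    dh0, ds0 = params.init_term
    out: dict[str, float] = {}
    for i in range(len(core) - 1):
        dinuc = core[i : i + 2]
        dh, ds = params.stack(dinuc)
        out[f"g{i + 1}g{i + 2}:{dinuc}"] = predict_tm(dh + dh0, ds + ds0, strand_conc)
    return out


def duplex_thermo(
    duplex: DuplexRecord,
    params: NNParameterSet | None = None,
    strand_conc: float = DEFAULT_CT_M,
    convention: str = "flank-average",
) -> ThermoResult:
    """NN thermodynamics of a validated duplex over its 19-bp core.

    dH (dS) is the sum of the 18 core stack increments plus initiation
    plus one terminal-A:U penalty per A:U (or U:A) core end.  The dTdT
    overhangs carry no increments.
    """
    params = params or default_parameters()
    core = _validated_core(duplex)
    dh, ds = params.init_term
    for i in range(len(core) - 1):
        sdh, sds = params.stack(core[i : i + 2])
        dh += sdh
        ds += sds
    for end in (core[0], core[-1]):
        if end in "AU":
            dh += params.terminal_AU_penalty[0]
            ds += params.terminal_AU_penalty[1]
    dg37 = dh - T37_K * ds / 1000.0
    return ThermoResult(
        duplex_id=duplex.duplex_id,
        dH=dh,
        dS=ds,
        dG37=dg37,
        tm_pred=predict_tm(dh, ds, strand_conc),
        positional_dE=positional_dE(core, params, convention),
        positional_convention=convention,
        stack_tm=stack_tm_features(core, params, strand_conc),
    )
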