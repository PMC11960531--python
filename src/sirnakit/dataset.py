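"""Curated siRNA duplex dataset: notation parsing, pairing, activity labels.

The sequence dialect follows the conventions used for 2'-modified siRNA
duplexes: unmodified RNA in upper case (``A C G U``), 2'-O-methyl in
lower case (``a c g u``), 2'-fluoro as ``Nf`` (``Af Cf Gf Uf``) and DNA
thymidine as ``dT``.  All strands in the packaged dataset are 21-mers:
a 19-nt base-paired core plus a 3' dTdT overhang.

The packaged table holds 15 parent/modified duplex pairs (11 targeting
SERPINA6, 4 targeting AGT) with in vitro IC50 (nM) and UV-melting Tm
(degrees C).  A modified duplex is labelled *inactive* when its IC50 is
not measurable (censored at 100 nM) or when the modification raises
IC50 at least 100-fold over the parent; otherwise it is *active*.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Sugar",
    "Nucleotide",
    "ModifiedStrand",
    "DuplexRecord",
    "DuplexPair",
    "ActivityLabel",
    "AlignmentResult",
    "ParseError",
    "parse_strand",
    "to_notation",
    "align_duplex",
    "classify_activity",
    "loss_category",
    "load_table1",
    "read_strand_fasta",
    "write_strand_fasta",
]

TABLE1_SHA256 = "e74aeef1de17c0d2df055befa053a9a696c146210c76ad783da1529c102602a5"

CENSOR_MARKER = ">100"
#: censoring threshold in nM implied by the marker
CENSOR_LIMIT_NM = 100.0
#: fold-change at or above which a measurable modified duplex is inactive
INACTIVE_FOLD = 100.0

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "T": "A"}


class Sugar(str, Enum):
    """Sugar chemistry of a nucleotide residue."""

    OH = "ribose-2'OH"
    OME = "ribose-2'OMe"
    F = "ribose-2'F"
    DEOXY = "deoxyribose"


class ParseError(ValueError):
    """Raised for malformed strand notation; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class Nucleotide:
    base: str  # A/C/G/U/T
    sugar: Sugar
    position: int  # 1-based from the 5' end

    def __post_init__(self) -> None:
        if self.base not in "ACGUT":
            raise ValueError(f"unknown base {self.base!r}")
        if self.base == "T" and self.sugar is not Sugar.DEOXY:
            raise ValueError("T occurs only with deoxyribose")
        if self.base == "U" and self.sugar is Sugar.DEOXY:
            raise ValueError("U never occurs with deoxyribose")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass(frozen=True)
class ModifiedStrand:
    """An annotated 5'->3' strand (sequence + sugar chemistry)."""

    id: str
    role: str  # "guide" | "passenger"
    residues: tuple[Nucleotide, ...]

    def __post_init__(self) -> None:
        if self.role not in ("guide", "passenger"):
            raise ValueError(f"role must be guide or passenger, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def positions_with(self, sugar: Sugar) -> tuple[int, ...]:
        return tuple(r.position for r in self.residues if r.sugar is sugar)

    @property
    def notation(self) -> str:
        return to_notation(self)


@dataclass(frozen=True)
class DuplexRecord:
    pair_id: str
    variant: str  # "parent" | "modified"
    guide: ModifiedStrand
    passenger: ModifiedStrand
    ic50_nM: float | None  # None iff censored
    ic50_censored: bool
    tm_C: float
    target: str

    def __post_init__(self) -> None:
        if self.variant not in ("parent", "modified"):
            raise ValueError(f"variant must be parent or modified, got {self.variant!r}")
        if len(self.guide) != len(self.passenger):
            raise ValueError("guide and passenger must have equal length")
        if self.ic50_censored != (self.ic50_nM is None):
            raise ValueError("censored IC50 carries no numeric value")
        if self.ic50_nM is not None and self.ic50_nM <= 0:
            raise ValueError("IC50 must be positive")

    @property
    def duplex_id(self) -> str:
        return f"{self.pair_id}{'m' if self.variant == 'modified' else ''}"


@dataclass(frozen=True)
class DuplexPair:
    """A parent duplex matched with its chemically modified counterpart."""

    pair_id: str
    parent: DuplexRecord
    modified: DuplexRecord

    @property
    def delta_tm(self) -> float:
        """Tm(modified) - Tm(parent), degrees C."""
        return self.modified.tm_C - self.parent.tm_C


@dataclass(frozen=True)
class ActivityLabel:
    label: str  # "active" | "inactive"
    fold_change: float | None  # IC50,mod / IC50,par; None when censored


@dataclass
class AlignmentResult:
    """Designed Watson-Crick pairing map of a 21/21 duplex.

    ``pairs`` lists 1-based (guide_pos, passenger_pos) tuples for the 19
    core positions (gi pairs p(20-i)); ``overhang`` holds the unpaired
    3'-terminal positions of both strands; ``mismatches`` flags designed
    pairs whose bases are not complementary.
    """

    pairs: list[tuple[int, int]]
    overhang: dict[str, tuple[int, ...]]
    mismatches: list[tuple[int, int, str, str]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs) - len(self.mismatches)

    @property
    def valid(self) -> bool:
        return not self.mismatches


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "d":
            if text[i : i + 2] != "dT":
                raise ParseError(f"unknown token starting {text[i:i+2]!r}", i)
            yield "dT", i
            i += 2
        elif ch in "ACGU":
            if i + 1 < n and text[i + 1] == "f":
                yield ch + "f", i
                i += 2
            else:
                yield ch, i
                i += 1
        elif ch in "acgu":
            if i + 1 < n and text[i + 1] == "f":
                raise ParseError("'f' may not follow a lowercase (2'-OMe) letter", i + 1)
            yield ch, i
            i += 1
        else:
            raise ParseError(f"unknown token {ch!r}", i)


def parse_strand(text: str, role: str, strand_id: str = "") -> ModifiedStrand:
    """Parse dialect notation into a :class:`ModifiedStrand`.

    Tokens: ``A/C/G/U`` 2'-OH ribose, ``a/c/g/u`` 2'-OMe, ``Af/Cf/Gf/Uf``
    2'-F, ``dT`` DNA thymidine.  Raises :class:`ParseError` naming the
    offending character offset for anything else.
    """
    residues: list[Nucleotide] = []
    for pos, (token, _off) in enumerate(_tokenize(text), start=1):
        if token == "dT":
            residues.append(Nucleotide("T", Sugar.DEOXY, pos))
        elif token.endswith("f"):
            residues.append(Nucleotide(token[0], Sugar.F, pos))
        elif token.isupper():
            residues.append(Nucleotide(token, Sugar.OH, pos))
        else:
            residues.append(Nucleotide(token.upper(), Sugar.OME, pos))
    return ModifiedStrand(id=strand_id or text, role=role, residues=tuple(residues))


def to_notation(strand: ModifiedStrand) -> str:
    """Serialize a strand back to dialect notation (inverse of parse)."""
    out = []
    for r in strand.residues:
        if r.sugar is Sugar.DEOXY:
            out.append("d" + r.base)
        elif r.sugar is Sugar.F:
            out.append(r.base.upper() + "f")
        elif r.sugar is Sugar.OME:
            out.append(r.base.lower())
        else:
            out.append(r.base.upper())
    return "".join(out)


def align_duplex(guide: ModifiedStrand, passenger: ModifiedStrand) -> AlignmentResult:
    """Map designed Watson-Crick pairs gi <-> p(20-i), i = 1..19.

    Both strands must be 21-mers ending in dTdT.  Non-complementary
    designed pairs are reported in ``mismatches`` rather than raised.
    """
    if len(guide) != len(passenger):
        raise ValueError(
            f"length mismatch: guide {len(guide)} vs passenger {len(passenger)}"
        )
    if len(guide) != 21:
        raise ValueError(f"expected 21-mers, got length {len(guide)}")
    for strand in (guide, passenger):
        tail = strand.residues[-2:]
        if not all(r.base == "T" and r.sugar is Sugar.DEOXY for r in tail):
            raise ValueError(f"strand {strand.id!r} lacks the 3' dTdT overhang")

    pairs: list[tuple[int, int]] = []
    mismatches: list[tuple[int, int, str, str]] = []
    for gi in range(1, 20):
        pj = 20 - gi
        gb = guide.residues[gi - 1].base
        pb = passenger.residues[pj - 1].base
        pairs.append((gi, pj))
        if _COMPLEMENT[gb] != pb:
            mismatches.append((gi, pj, gb, pb))
    return AlignmentResult(
        pairs=pairs,
        overhang={"guide": (20, 21), "passenger": (20, 21)},
        mismatches=mismatches,
    )


def classify_activity(pair: DuplexPair) -> ActivityLabel:
    """Apply the activity rule to a parent/modified pair.

    Inactive iff the modified IC50 is censored (>100 nM, not measurable)
    or the fold-change IC50,mod/IC50,par is >= 100; active otherwise.
    """
    parent, modified = pair.parent, pair.modified
    if parent.ic50_censored or parent.ic50_nM is None:
        raise ValueError(f"{pair.pair_id}: parent IC50 must be numeric")
    if modified.ic50_censored:
        return ActivityLabel("inactive", None)
    if modified.ic50_nM is None:
        raise ValueError(f"{pair.pair_id}: modified IC50 missing")
    fold = modified.ic50_nM / parent.ic50_nM
    return ActivityLabel("inactive" if fold >= INACTIVE_FOLD else "active", fold)


def loss_category(pair: DuplexPair) -> str:
    """Three-way potency-loss bin for the modified duplex.

    ``censored``: IC50 not measurable; ``moderate``: measurable but
    >10-fold loss; ``unaffected``: at most 10-fold change.
    """
    if pair.modified.ic50_censored:
        return "censored"
    fold = pair.modified.ic50_nM / pair.parent.ic50_nM  # type: ignore[operator]
    return "moderate" if fold > 10.0 else "unaffected"


def _parse_ic50(text: str) -> tuple[float | None, bool]:
    text = text.strip()
    if text == CENSOR_MARKER:
        return None, True
    return float(text), False


def _records_from_rows(rows: Iterable[dict[str, str]]) -> list[DuplexPair]:
    by_pair: dict[str, dict[str, DuplexRecord]] = {}
    order: list[str] = []
    for row in rows:
        pair_id = row["pair_id"]
        variant = row["variant"]
        suffix = "m" if variant == "modified" else ""
        guide = parse_strand(row["guide_notation"], "guide", f"{pair_id}{suffix}-g")
        passenger = parse_strand(
            row["passenger_notation"], "passenger", f"{pair_id}{suffix}-p"
        )
        aln = align_duplex(guide, passenger)
        if not aln.valid:
            raise ValueError(f"{pair_id} {variant}: non-complementary designed pairs {aln.mismatches}")
        ic50, censored = _parse_ic50(row["ic50_nM"])
        rec = DuplexRecord(
            pair_id=pair_id,
            variant=variant,
            guide=guide,
            passenger=passenger,
            ic50_nM=ic50,
            ic50_censored=censored,
            tm_C=float(row["tm_C"]),
            target=row["target"],
        )
        if pair_id not in by_pair:
            by_pair[pair_id] = {}
            order.append(pair_id)
        by_pair[pair_id][variant] = rec
    pairs = []
    for pid in order:
        d = by_pair[pid]
        if set(d) != {"parent", "modified"}:
            raise ValueError(f"{pid}: expected one parent and one modified record")
        pairs.append(DuplexPair(pid, d["parent"], d["modified"]))
    return pairs


def load_table1(path: str | Path | None = None, check: bool = True) -> list[DuplexPair]:
    """Load the packaged duplex table (or a user table in the same layout).

    Columns: pair_id, variant, passenger_notation, guide_notation,
    ic50_nM (numeric or ``>100``), tm_C, target.  The packaged fixture's
    SHA-256 is verified unless ``check=False``.
    """
    if path is None:
        data = (
            resources.files("sirnakit").joinpath("data/table1.tsv").read_bytes()
        )
        if check and hashlib.sha256(data).hexdigest() != TABLE1_SHA256:
            raise IOError("packaged duplex table failed its checksum")
    else:
        data = Path(path).read_bytes()
    lines = [ln for ln in data.decode().splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    rows = [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
    return _records_from_rows(rows)


def read_strand_fasta(path: str | Path) -> list[ModifiedStrand]:
    """Read FASTA-like records whose headers carry ``id|role|variant``."""
    strands = []
    header: str | None = None
    seq_parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        fields = header.split("|")
        if len(fields) < 2:
            raise ValueError(f"header {header!r} must carry id|role[|variant]")
        strands.append(parse_strand("".join(seq_parts), fields[1], fields[0]))

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:]
            seq_parts = []
        else:
            seq_parts.append(line)
    flush()
    return strands


def write_strand_fasta(strands: Iterable[ModifiedStrand], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in strands:
            fh.write(f">{s.id}|{s.role}\n{to_notation(s)}\n")
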