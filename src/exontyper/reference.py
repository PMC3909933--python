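"""Allele reference, primer library, and the exon allele group structures.

Short-amplicon HLA typing cannot distinguish alleles that are identical
over the sequenced exon, so alleles are grouped into Exon Allele Groups
(EAGs): the alleles of one locus sharing a byte-identical exon sequence.
Because a read covers only part of the exon, EAGs that agree over the
read-covered span collapse further into partial EAGs (PEAGs), built
separately for the forward and the reverse read direction.  Reads are then
matched against PEAGs and evidence is accumulated per EAG.

All coordinates are 0-based half-open internally; exon numbers are 1-based
labels.  Reverse-direction PEAG sequences are stored reverse-complemented
so that every tree walk runs 5'→3' in read orientation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .trie import MatchTree, build_primer_tree

__all__ = [
    "AlleleSequence",
    "PrimerDef",
    "EAG",
    "PEAG",
    "ReferenceFormatError",
    "parse_allele_name",
    "load_allele_db",
    "load_primer_library",
    "write_reference",
    "write_primer_library",
    "build_eags",
    "build_peags",
    "ReferenceModel",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceFormatError(ValueError):
    """Malformed allele name, exon table, or primer library."""


def parse_allele_name(name: str) -> tuple[str, tuple[str, ...]]:
    """Split ``LOCUS*gg:pp[:...]`` into locus and ≥2 colon-separated fields."""
    if "*" not in name:
        raise ReferenceFormatError(f"allele name '{name}' lacks a '*' separator")
    locus, _, rest = name.partition("*")
    fields = tuple(rest.split(":"))
    if not locus or len(fields) < 2 or any(not f for f in fields):
        raise ReferenceFormatError(
            f"allele name '{name}' does not parse into locus + ≥2 fields"
        )
    return locus, fields


@dataclass
class AlleleSequence:
    """One reference allele: per-exon sequences plus adjacent intronic flanks.

    ``flank_seqs`` is keyed by ``(exon, side)`` with side ``"5p"`` (intron
    upstream of the exon) or ``"3p"`` (downstream).
    """

    name: str
    locus: str
    exon_seqs: dict[int, str]
    flank_seqs: dict[tuple[int, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        locus, _ = parse_allele_name(self.name)
        if locus != self.locus:
            raise ReferenceFormatError(
                f"allele '{self.name}': name locus '{locus}' != field '{self.locus}'"
            )
        for exon, seq in self.exon_seqs.items():
            if not seq or not set(seq) <= VALID_BASES:
                raise ReferenceFormatError(
                    f"allele '{self.name}' exon {exon}: empty or non-ACGT sequence"
                )


@dataclass(frozen=True)
class PrimerDef:
    """A target-specific primer sitting in the intron flanking its exon."""

    id: str
    locus: str
    exon: int
    direction: str  # "forward" | "reverse"
    sequence: str

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ReferenceFormatError(
                f"primer '{self.id}': direction must be forward/reverse"
            )
        if len(self.sequence) < 15:
            raise ReferenceFormatError(
                f"primer '{self.id}': sequence shorter than 15 bases"
            )


def _group_hash(members: Iterable[str]) -> str:
    joined = "|".join(sorted(members))
    return hashlib.sha1(joined.encode()).hexdigest()[:8]


@dataclass(frozen=True)
class EAG:
    """Exon Allele Group: alleles of one locus identical over one exon."""

    id: str
    locus: str
    exon: int
    exon_sequence: str
    members: frozenset[str]


@dataclass(frozen=True)
class PEAG:
    """Partial EAG: EAGs identical over the read-covered span, one direction.

    ``partial_sequence`` is stored in read orientation (reverse-direction
    partials are reverse-complemented).
    """

    id: str
    locus: str
    exon: int
    direction: str
    partial_sequence: str
    member_eags: frozenset[str]


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def load_allele_db(reference_fasta, exon_table) -> list[AlleleSequence]:
    """Load a FASTA of allele records plus a per-allele exon-coordinate TSV.

    The TSV has columns ``allele exon start end`` with 0-based half-open
    coordinates into the FASTA record.  Intronic flanks are the regions
    between exon boundaries (or the record ends).
    """
    coords = pd.read_csv(
        exon_table,
        sep="\t",
        dtype={"allele": str, "exon": int, "start": int, "end": int},
    )
    required = {"allele", "exon", "start", "end"}
    if not required <= set(coords.columns):
        raise ReferenceFormatError(
            f"exon table must have columns {sorted(required)}, got {list(coords.columns)}"
        )
    by_allele: dict[str, list] = {}
    for row in coords.itertuples(index=False):
        by_allele.setdefault(row.allele, []).append((row.exon, row.start, row.end))

    alleles: list[AlleleSequence] = []
    for record in SeqIO.parse(str(reference_fasta), "fasta"):
        name = record.id
        locus, _ = parse_allele_name(name)  # raises on malformed names
        seq = str(record.seq).upper()
        entries = by_allele.get(name)
        if not entries:
            raise ReferenceFormatError(f"allele '{name}' has no exon-table entries")
        entries.sort(key=lambda t: t[1])
        exon_seqs: dict[int, str] = {}
        flank_seqs: dict[tuple[int, str], str] = {}
        for i, (exon, start, end) in enumerate(entries):
            if not (0 <= start < end <= len(seq)):
                raise ReferenceFormatError(
                    f"allele '{name}' exon {exon}: coordinates [{start},{end}) "
                    f"outside sequence of length {len(seq)}"
                )
            exon_seqs[exon] = seq[start:end]
            prev_end = entries[i - 1][2] if i > 0 else 0
            next_start = entries[i + 1][1] if i + 1 < len(entries) else len(seq)
            flank_seqs[(exon, "5p")] = seq[prev_end:start]
            flank_seqs[(exon, "3p")] = seq[end:next_start]
        alleles.append(AlleleSequence(name, locus, exon_seqs, flank_seqs))
    return alleles


def write_reference(alleles: Sequence[AlleleSequence], fasta_path, exon_table_path) -> None:
    """Write alleles back out as FASTA + exon-coordinate TSV (round-trippable).

    The record is assembled as 5'flank + exon + 3'flank per exon in
    ascending exon order.  Between consecutive exons both flanks are
    emitted (3' of the earlier, then 5' of the later), so on re-loading the
    full inter-exon region is seen as the flank of either neighbor; the
    primer-proximal flank ends are preserved exactly.
    """
    rows = []
    with open(fasta_path, "w") as fh:
        for allele in alleles:
            parts: list[str] = []
            pos = 0
            exons = sorted(allele.exon_seqs)
            for exon in exons:
                five = allele.flank_seqs.get((exon, "5p"), "")
                parts.append(five)
                pos += len(five)
                exon_seq = allele.exon_seqs[exon]
                rows.append((allele.name, exon, pos, pos + len(exon_seq)))
                parts.append(exon_seq)
                pos += len(exon_seq)
                three = allele.flank_seqs.get((exon, "3p"), "")
                parts.append(three)
                pos += len(three)
            fh.write(f">{allele.name}\n{''.join(parts)}\n")
    pd.DataFrame(rows, columns=["allele", "exon", "start", "end"]).to_csv(
        exon_table_path, sep="\t", index=False
    )


def load_primer_library(path) -> list[PrimerDef]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "locus": str, "exon": int})
    primers = [
        PrimerDef(r.id, r.locus, int(r.exon), r.direction, r.sequence.upper())
        for r in df.itertuples(index=False)
    ]
    seen: dict[tuple, str] = {}
    for p in primers:
        key = (p.locus, p.exon, p.direction, p.sequence)
        if key in seen:
            raise ReferenceFormatError(
                f"duplicate primer definition: '{seen[key]}' and '{p.id}'"
            )
        seen[key] = p.id
    return primers


def write_primer_library(primers: Sequence[PrimerDef], path) -> None:
    pd.DataFrame(
        [(p.id, p.locus, p.exon, p.direction, p.sequence) for p in primers],
        columns=["id", "locus", "exon", "direction", "sequence"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# EAG / PEAG construction
# ---------------------------------------------------------------------------

def build_eags(
    alleles: Iterable[AlleleSequence], locus: str, exon: int
) -> list[EAG]:
    """Partition the alleles of one locus by exon-sequence identity.

    Two alleles share an EAG iff their sequences over the exon are
    string-identical.  Ids are deterministic (hash of sorted member names)
    so partitions are byte-comparable across runs.
    """
    groups: dict[str, set[str]] = {}
    for allele in alleles:
        if allele.locus != locus or exon not in allele.exon_seqs:
            continue
        groups.setdefault(allele.exon_seqs[exon], set()).add(allele.name)
    eags = [
        EAG(
            id=f"{locus}:e{exon}:{_group_hash(members)}",
            locus=locus,
            exon=exon,
            exon_sequence=seq,
            members=frozenset(members),
        )
        for seq, members in groups.items()
    ]
    eags.sort(key=lambda e: min(e.members))
    return eags


def _partial_region(
    eag: EAG,
    direction: str,
    read_span: int,
    flank: str,
) -> str:
    """Read-covered reference span for one EAG in one direction.

    Forward reads enter at the exon start and may run into the downstream
    intron; reverse reads enter at the exon end and may run into the
    upstream intron.  The returned string is in read orientation.
    """
    exon_seq = eag.exon_sequence
    if direction == "forward":
        region = exon_seq + flank
        return region[:read_span]
    region = flank + exon_seq
    return reverse_complement(region[-read_span:] if read_span < len(region) else region)


def build_peags(
    eags: Sequence[EAG],
    read_span: int,
    direction: str,
    alleles: Optional[Mapping[str, AlleleSequence]] = None,
) -> list[PEAG]:
    """Merge EAGs with identical read-covered partial sequences into PEAGs.

    When ``read_span`` exceeds the exon length the covered span extends into
    the intronic flank, taken from the lexicographically first member allele
    (flanks are assumed conserved within a locus — primers sit there).
    """
    if read_span <= 0:
        raise ValueError("read_span must be positive")
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    side = "3p" if direction == "forward" else "5p"
    groups: dict[str, set[str]] = {}
    meta: dict[str, EAG] = {}
    for eag in eags:
        flank = ""
        if read_span > len(eag.exon_sequence):
            if alleles is None:
                raise ValueError(
                    "read_span exceeds exon length; allele map needed for flanks"
                )
            rep = alleles[min(eag.members)]
            flank = rep.flank_seqs.get((eag.exon, side), "")
        partial = _partial_region(eag, direction, read_span, flank)
        groups.setdefault(partial, set()).add(eag.id)
        meta[eag.id] = eag
    tag = "f" if direction == "forward" else "r"
    peags = []
    for partial, member_ids in groups.items():
        any_eag = meta[min(member_ids)]
        peags.append(
            PEAG(
                id=f"{any_eag.locus}:e{any_eag.exon}:{tag}:{_group_hash(member_ids)}",
                locus=any_eag.locus,
                exon=any_eag.exon,
                direction=direction,
                partial_sequence=partial,
                member_eags=frozenset(member_ids),
            )
        )
    peags.sort(key=lambda p: min(p.member_eags))
    return peags


# ---------------------------------------------------------------------------
# bundled model
# ---------------------------------------------------------------------------

class ReferenceModel:
    """Precomputed matching structures for one reference + primer library.

    Holds the allele map, per-(locus, exon) EAGs, per-(locus, exon,
    direction) PEAGs and their match trees, and the primer tree.
    """

    def __init__(
        self,
        alleles: Sequence[AlleleSequence],
        primers: Sequence[PrimerDef],
        read_length: int = 251,
    ) -> None:
        self.alleles: dict[str, AlleleSequence] = {a.name: a for a in alleles}
        self.primers: list[PrimerDef] = list(primers)
        self.read_length = read_length
        self.loci = sorted({a.locus for a in alleles})

        max_primer = max((len(p.sequence) for p in primers), default=0)
        # span of reference sequence a clipped read can cover
        self.read_span = read_length - max_primer if primers else read_length

        self.eags: dict[tuple[str, int], list[EAG]] = {}
        self.eag_by_id: dict[str, EAG] = {}
        self.peags: dict[tuple[str, int, str], list[PEAG]] = {}
        self.peag_trees: dict[tuple[str, int, str], MatchTree] = {}
        self.peag_members: dict[str, frozenset[str]] = {}

        exon_keys = sorted(
            {(a.locus, e) for a in alleles for e in a.exon_seqs}
        )
        for locus, exon in exon_keys:
            eags = build_eags(alleles, locus, exon)
            self.eags[(locus, exon)] = eags
            for eag in eags:
                self.eag_by_id[eag.id] = eag
            for direction in ("forward", "reverse"):
                peags = build_peags(eags, self.read_span, direction, self.alleles)
                self.peags[(locus, exon, direction)] = peags
                exon_len = len(eags[0].exon_sequence) if eags else 0
                flank_start = exon_len if self.read_span > exon_len else None
                tree = MatchTree.from_sequences(
                    [(p.partial_sequence, p.id) for p in peags],
                    flank_start=flank_start,
                )
                self.peag_trees[(locus, exon, direction)] = tree
                for p in peags:
                    self.peag_members[p.id] = p.member_eags

        self.primer_tree = build_primer_tree(self.primers) if self.primers else None
        self.primer_by_id = {p.id: p for p in self.primers}
        self.eag_members: dict[str, frozenset[str]] = {
            eag_id: eag.members for eag_id, eag in self.eag_by_id.items()
        }

    @classmethod
    def from_files(
        cls, reference_fasta, exon_table, primer_tsv, read_length: int = 251
    ) -> "ReferenceModel":
        return cls(
            load_allele_db(reference_fasta, exon_table),
            load_primer_library(primer_tsv),
            read_length=read_length,
        )

    def allele_eag(self, locus: str, exon: int, allele_name: str) -> Optional[EAG]:
        for eag in self.eags.get((locus, exon), []):
            if allele_name in eag.members:
                return eag
        return None

    def exon_length(self, locus: str, exon: int) -> int:
        eags = self.eags[(locus, exon)]
        return len(eags[0].exon_sequence)
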