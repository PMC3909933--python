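"""Truth-based read classification for primer-set evaluation.

When a primer set is tested against samples of *known* genotype, every
read can be audited directly: a 10-mer prescreen finds the most similar
reference allele (up to 10 mismatches), a base-by-base Q-value comparison
assigns the read to one of the two truth alleles, and reads whose
mismatches are explained by a single template switch between the two
alleles are flagged as PCR crossover products.  Per primer set the allele
balance (minor/major read ratio, QC pass at ≥ 20%) and the crossover rate
are summarized.

Rules (Q_sum = sum of Phred scores over mismatched positions):
* Q_sum > 80 against both truth alleles → not matching (crossover rescue
  is attempted first);
* Q_sum worse by > 50 than against the prescreen-best reference allele →
  other HLA allele;
* otherwise the read goes to the lower-Q_sum allele (tie → allele 1), and
  ≥ 2 bases with Q > 25 agreeing with the *alternate* allele make it
  "allele n with crossover".
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .readio import QualityRead

__all__ = [
    "QcConfig",
    "ReadCategory",
    "BalanceReport",
    "KmerIndex",
    "kmer_prescreen",
    "classify_read_qsum",
    "detect_crossover_read",
    "summarize_primer_set",
    "classify_run_pairs",
    "amplicon_frames",
    "PrimerSetSummary",
]

def amplicon_frames(reference) -> dict[tuple[str, int, str], dict[str, str]]:
    """Per (locus, exon, direction): allele → primer-clipped amplicon
    sequence in read orientation, the frame Q_sum comparisons run in."""
    from .reference import reverse_complement

    span = reference.read_span
    frames: dict[tuple[str, int, str], dict[str, str]] = {}
    for allele in reference.alleles.values():
        for exon, exon_seq in allele.exon_seqs.items():
            fwd = (exon_seq + allele.flank_seqs.get((exon, "3p"), ""))[:span]
            region = allele.flank_seqs.get((exon, "5p"), "") + exon_seq
            rev = reverse_complement(region[-span:] if span < len(region) else region)
            frames.setdefault((allele.locus, exon, "forward"), {})[allele.name] = fwd
            frames.setdefault((allele.locus, exon, "reverse"), {})[allele.name] = rev
    return frames


CATEGORIES = (
    "allele1",
    "allele2",
    "allele1_with_crossover",
    "allele2_with_crossover",
    "other_hla_allele",
    "not_matched",
)


@dataclass(slots=True)
class QcConfig:
    kmer_size: int = 10
    max_mismatches: int = 10  # prescreen: reads beyond this are "not matched"
    qsum_not_matching: float = 80.0  # Q_sum above this → not matching
    qsum_other_allele_delta: float = 50.0  # worse than db-best by this → other allele
    crossover_min_bases: int = 2  # alternate-agreeing bases needed ...
    crossover_min_q: float = 25.0  # ... each with Q above this
    balance_pass_ratio: float = 0.20  # batch QC: minor/major ≥ 20%


@dataclass(slots=True)
class ReadCategory:
    read_id: str
    category: str
    q_sum_allele1: float
    q_sum_allele2: float
    crossover_positions: tuple[int, ...] = ()
    nearest_db_allele: str = ""
    nearest_db_mismatches: int = -1


class KmerIndex:
    """10-mer index over reference amplicon sequences for the prescreen."""

    def __init__(self, sequences: Mapping[str, str], k: int = 10) -> None:
        self.k = k
        self.sequences = dict(sequences)
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].append((name, i))


def _ungapped_mismatches(read_seq: str, ref_seq: str, offset: int) -> int:
    """Mismatch count of the read placed at ``offset`` on the reference.

    Read bases falling outside the reference count as mismatches.
    """
    mm = 0
    for i, base in enumerate(read_seq):
        j = offset + i
        if 0 <= j < len(ref_seq):
            if ref_seq[j] != base:
                mm += 1
        else:
            mm += 1
    return mm


def kmer_prescreen(
    read: QualityRead,
    index: KmerIndex,
    cfg: Optional[QcConfig] = None,
) -> Optional[tuple[str, int, int]]:
    """Most similar reference allele by shared 10-mers, or ``None``.

    Candidates are ranked by shared k-mer count; the best is aligned
    ungapped at the offset implied by the k-mer diagonal vote.  More than
    ``max_mismatches`` mismatches → not matched (``None``).  Returns
    (allele, offset, mismatches).
    """
    cfg = cfg or QcConfig()
    k = index.k
    seq = read.sequence
    votes: Counter = Counter()
    for i in range(0, len(seq) - k + 1):
        for name, j in index.index.get(seq[i : i + k], ()):
            votes[(name, j - i)] += 1
    if not votes:
        return None
    # most shared k-mers on one diagonal; deterministic tie-break
    (name, offset), _ = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    mm = _ungapped_mismatches(seq, index.sequences[name], offset)
    if mm > cfg.max_mismatches:
        return None
    return (name, offset, mm)


def _qsum(read: QualityRead, ref_seq: str) -> float:
    """Quality-weighted mismatch burden of the read against a reference,
    both anchored at position 0 (primer-clipped amplicon frame)."""
    n = min(len(read.sequence), len(ref_seq))
    total = 0.0
    seq, quals = read.sequence, read.quals
    for i in range(n):
        if seq[i] != ref_seq[i]:
            total += float(quals[i])
    return total


def detect_crossover_read(
    read: QualityRead,
    assigned_seq: str,
    alternate_seq: str,
    cfg: Optional[QcConfig] = None,
    homozygous: bool = False,
) -> tuple[bool, tuple[int, ...]]:
    """Positions where the read leaves the assigned allele *for* the
    alternate allele with good quality; ≥ 2 such bases mean a template
    switch.  Inapplicable (always False) for homozygous truth."""
    cfg = cfg or QcConfig()
    if homozygous:
        return False, ()
    n = min(len(read.sequence), len(assigned_seq), len(alternate_seq))
    switches = tuple(
        i
        for i in range(n)
        if read.sequence[i] != assigned_seq[i]
        and read.sequence[i] == alternate_seq[i]
        and float(read.quals[i]) > cfg.crossover_min_q
    )
    return len(switches) >= cfg.crossover_min_bases, switches


def _best_chimera_qsum(read: QualityRead, seq_a: str, seq_b: str) -> float:
    """Q_sum of the best single-breakpoint a/b chimera explaining the read."""
    n = min(len(read.sequence), len(seq_a), len(seq_b))
    quals = read.quals
    mm_a = np.fromiter(
        (quals[i] if read.sequence[i] != seq_a[i] else 0.0 for i in range(n)),
        dtype=float,
        count=n,
    )
    mm_b = np.fromiter(
        (quals[i] if read.sequence[i] != seq_b[i] else 0.0 for i in range(n)),
        dtype=float,
        count=n,
    )
    # prefix from a, suffix from b (and the reverse): cumulative sums over b
    best = float("inf")
    for first, second in ((mm_a, mm_b), (mm_b, mm_a)):
        pref = np.concatenate(([0.0], np.cumsum(first)))
        suff = np.concatenate((np.cumsum(second[::-1])[::-1], [0.0]))
        best = min(best, float(np.min(pref + suff)))
    return best


def classify_read_qsum(
    read: QualityRead,
    allele1_seq: str,
    allele2_seq: str,
    prescreen_hit: Optional[tuple[str, int, int]],
    truth_alleles: tuple[str, str],
    index: Optional[KmerIndex] = None,
    cfg: Optional[QcConfig] = None,
) -> ReadCategory:
    """Assign one primer-clipped read to a truth-based category."""
    cfg = cfg or QcConfig()
    homozygous = truth_alleles[0] == truth_alleles[1]
    q1 = _qsum(read, allele1_seq)
    q2 = _qsum(read, allele2_seq)
    best_truth = min(q1, q2)

    nearest = prescreen_hit[0] if prescreen_hit else ""
    nearest_mm = prescreen_hit[2] if prescreen_hit else -1

    # worse by >50 than an outside reference allele → other HLA allele
    if (
        prescreen_hit is not None
        and index is not None
        and nearest not in truth_alleles
    ):
        q_db = _qsum(read, index.sequences[nearest])
        if best_truth - q_db > cfg.qsum_other_allele_delta:
            return ReadCategory(read.read_id, "other_hla_allele", q1, q2, (), nearest, nearest_mm)

    if best_truth > cfg.qsum_not_matching:
        # rescue: mismatches explained by a single template switch?
        if not homozygous:
            chim = _best_chimera_qsum(read, allele1_seq, allele2_seq)
            if chim <= cfg.qsum_not_matching:
                n = 1 if q1 <= q2 else 2
                assigned = allele1_seq if n == 1 else allele2_seq
                alternate = allele2_seq if n == 1 else allele1_seq
                is_x, pos = detect_crossover_read(read, assigned, alternate, cfg)
                if is_x:
                    return ReadCategory(
                        read.read_id, f"allele{n}_with_crossover", q1, q2, pos, nearest, nearest_mm
                    )
        return ReadCategory(read.read_id, "not_matched", q1, q2, (), nearest, nearest_mm)

    n = 1 if q1 <= q2 else 2  # lower Q_sum wins; ties to allele 1
    assigned = allele1_seq if n == 1 else allele2_seq
    alternate = allele2_seq if n == 1 else allele1_seq
    is_x, pos = detect_crossover_read(read, assigned, alternate, cfg, homozygous=homozygous)
    category = f"allele{n}_with_crossover" if is_x else f"allele{n}"
    return ReadCategory(read.read_id, category, q1, q2, pos, nearest, nearest_mm)


def classify_run_pairs(
    pairs,
    truth_alleles: tuple[str, str],
    reference,
    cfg: Optional[QcConfig] = None,
):
    """Truth-based classification of whole mate pairs against a reference.

    Each mate is primer-recognized, clipped, prescreened and Q_sum
    classified in its own amplicon frame; the pair-level category is
    crossover when either mate shows a template switch, otherwise the
    allele call of the mates (forward mate preferred), "not_matched" when
    neither mate matches.  Returns (pair_categories, read_categories).
    """
    from .primers import PrimerRecognizer, RecognitionConfig, clip_primer

    cfg = cfg or QcConfig()
    a1, a2 = truth_alleles
    recognizer = PrimerRecognizer(
        reference.primers, reference.primer_tree, RecognitionConfig()
    )
    frames = amplicon_frames(reference)
    indexes: dict[tuple[int, str], KmerIndex] = {}
    for (locus, exon, direction), seqs in frames.items():
        key = (exon, direction)
        merged = indexes.get(key)
        if merged is None:
            all_seqs: dict[str, str] = {}
            for (l2, e2, d2), m in frames.items():
                if (e2, d2) == key:
                    all_seqs.update(m)
            indexes[key] = KmerIndex(all_seqs, k=cfg.kmer_size)

    pair_categories: list[str] = []
    read_categories: list[ReadCategory] = []
    for pair in pairs:
        mate_cats: list[str] = []
        for read in pair:
            pm = recognizer.recognize(read)
            if not pm.matched:
                mate_cats.append("not_matched")
                continue
            primer = recognizer.primer_by_id[pm.primer_id]
            insert = clip_primer(read, pm)
            seqs = frames[(primer.locus, primer.exon, primer.direction)]
            index = indexes[(primer.exon, primer.direction)]
            hit = kmer_prescreen(insert, index, cfg)
            cat = classify_read_qsum(
                insert, seqs[a1], seqs[a2], hit, truth_alleles, index, cfg
            )
            read_categories.append(cat)
            mate_cats.append(cat.category)
        if any(c.endswith("_with_crossover") for c in mate_cats):
            pair_categories.append("crossover")
        elif mate_cats[0] in ("allele1", "allele2"):
            pair_categories.append(mate_cats[0])
        elif len(mate_cats) > 1 and mate_cats[1] in ("allele1", "allele2"):
            pair_categories.append(mate_cats[1])
        elif "other_hla_allele" in mate_cats:
            pair_categories.append("other_hla_allele")
        else:
            pair_categories.append("not_matched")
    return pair_categories, read_categories


@dataclass
class BalanceReport:
    primer_set_id: str
    sample_id: str
    n_allele1: int
    n_allele2: int
    minor_major_ratio: float
    pass_qc: bool
    heterozygous: bool = True


@dataclass
class PrimerSetSummary:
    balance: BalanceReport
    n_matched: int
    n_crossover: int
    n_other: int
    n_not_matched: int
    crossover_rate: float
    category_counts: dict[str, int] = field(default_factory=dict)


def summarize_primer_set(
    categories: Sequence[ReadCategory],
    primer_set_id: str = "",
    sample_id: str = "",
    heterozygous: bool = True,
    cfg: Optional[QcConfig] = None,
) -> PrimerSetSummary:
    """Allele balance and crossover rate for one sample-amplicon.

    Crossover reads count toward their assigned allele in the balance
    ratio; the crossover rate is crossover reads over matched reads
    (matched = assigned to either allele, including crossovers).  The 20%
    balance rule applies only to heterozygous truth.
    """
    cfg = cfg or QcConfig()
    counts = Counter(c.category for c in categories)
    n1 = counts["allele1"] + counts["allele1_with_crossover"]
    n2 = counts["allele2"] + counts["allele2_with_crossover"]
    n_x = counts["allele1_with_crossover"] + counts["allele2_with_crossover"]
    matched = n1 + n2
    if n1 == 0 or n2 == 0:
        ratio = 0.0
    else:
        ratio = min(n1, n2) / max(n1, n2)
    pass_qc = (ratio >= cfg.balance_pass_ratio) if heterozygous else True
    return PrimerSetSummary(
        balance=BalanceReport(
            primer_set_id=primer_set_id,
            sample_id=sample_id,
            n_allele1=n1,
            n_allele2=n2,
            minor_major_ratio=ratio,
            pass_qc=pass_qc,
            heterozygous=heterozygous,
        ),
        n_matched=matched,
        n_crossover=n_x,
        n_other=counts["other_hla_allele"],
        n_not_matched=counts["not_matched"],
        crossover_rate=(n_x / matched) if matched else 0.0,
        category_counts=dict(counts),
    )
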