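"""Exon combination, safeguards, rating and the final genotype call.

Per exon, at most two EAGs classified as results (plus co-amplificates
when nothing else yields a consistent genotype) define the candidate
allele content of the two chromosomes.  A genotype is a pairing of one
EAG per chromosome per exon such that an allele exists carrying exactly
those exon sequences — the allele set per chromosome is the intersection
across exons of the chosen EAGs' member sets.  When exon 2 and exon 3
admit more than one consistent cross-pairing the ambiguity cannot be
resolved (exon shuffling) and all pairings are reported.

Safeguards: exons with fewer than 20 result reads are ignored; homozygous
calls need at least 100 reads (20-fold above the ~5-read detection limit,
covering amplification imbalance up to 20:1); a second allele down to 2%
of the dominant allele's reads (absolute floor 5) counts as genuinely
present.  The call is rated by three fractions (successful primer
matches, EAG association, reads contributing to the result), each mapped
through a two-threshold linear ramp; the rating is the product and only a
rating of exactly 1 with no blocking flags is submitted automatically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .matching import EagScore

__all__ = [
    "ExonResult",
    "GenotypeCall",
    "RatingConfig",
    "CallingConfig",
    "Pairing",
    "combine_exons",
    "guard_homozygous",
    "detect_suppressed_allele",
    "SuppressedAlleleReport",
    "rate_result",
    "finalize",
    "encode_ambiguity",
]


@dataclass
class ExonResult:
    """Per-exon outcome of classification feeding the combiner."""

    locus: str
    exon: int
    result_eags: list[str]  # ranked, at most 2
    coamp_eags: list[str] = field(default_factory=list)
    total_result_reads: int = 0
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.result_eags) > 2:
            raise ValueError("an ExonResult carries at most 2 result EAGs")


@dataclass
class Pairing:
    """One consistent chromosome assignment across the combined exons."""

    group1: frozenset[str]
    group2: frozenset[str]
    per_exon: dict[int, tuple[str, str]]  # exon -> (eag chr1, eag chr2)

    @property
    def homozygous(self) -> bool:
        return all(a == b for a, b in self.per_exon.values())


@dataclass
class GenotypeCall:
    sample: str
    locus: str
    allele_groups: tuple[frozenset[str], frozenset[str]]
    zygosity: str  # heterozygous | homozygous | blocked_homozygous
    rating: float = 0.0
    status: str = "review"  # auto | review | edit_required | failed
    pairings: list[Pairing] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    metrics: dict[str, float] = field(default_factory=dict)
    failure_reason: str = ""
    ignored_exons: list[int] = field(default_factory=list)

    @property
    def genotype_string(self) -> str:
        if self.status == "failed" or not self.allele_groups[0]:
            return ""
        return encode_ambiguity(self.allele_groups)


@dataclass
class RatingConfig:
    """Two-threshold ramps per rating parameter plus safeguard thresholds."""

    primer_match: tuple[float, float] = (0.80, 0.95)
    eag_association: tuple[float, float] = (0.70, 0.90)
    contributing_reads: tuple[float, float] = (0.80, 0.95)

    def __post_init__(self) -> None:
        for name in ("primer_match", "eag_association", "contributing_reads"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"rating thresholds for {name} need 0 ≤ lower < upper ≤ 1")


@dataclass
class CallingConfig:
    min_exon_reads: int = 20  # exons below this result-read sum are ignored
    min_homozygous_reads: int = 100  # block homozygous calls below this
    suppressed_rel: float = 0.02  # second allele detectable down to 2%
    suppressed_abs: int = 5  # ... but never below 5 best-match reads
    rating: RatingConfig = field(default_factory=RatingConfig)


def _exon_assignments(retained: Sequence[str]) -> list[tuple[str, str]]:
    if len(retained) == 1:
        return [(retained[0], retained[0])]
    return list(itertools.permutations(retained, 2))


def combine_exons(
    exon_results: Mapping[int, ExonResult],
    eag_members: Mapping[str, frozenset[str]],
    cfg: Optional[CallingConfig] = None,
) -> tuple[list[Pairing], set[str], list[int], bool]:
    """Enumerate genotypes consistent with every informative exon.

    Returns (pairings, flags, ignored_exons, used_coamp).  Exons whose
    result EAGs sum to fewer than ``min_exon_reads`` reads are ignored.
    When no consistent pairing exists from result EAGs alone,
    co-amplificate EAGs are added one at a time in rank order and the
    combination is retried (off-target labels can mask a true allele when
    a real allele's sequence coincides with a paralog's).
    """
    cfg = cfg or CallingConfig()
    flags: set[str] = set()
    usable = {
        exon: res
        for exon, res in exon_results.items()
        if res.total_result_reads >= cfg.min_exon_reads and res.result_eags
    }
    ignored = sorted(set(exon_results) - set(usable))
    if not usable:
        return [], {"low_reads"}, ignored, False

    def enumerate_pairings(retained_by_exon: Mapping[int, Sequence[str]]) -> list[Pairing]:
        exons = sorted(retained_by_exon)
        options = [_exon_assignments(retained_by_exon[e]) for e in exons]
        seen: set[frozenset] = set()
        found: list[Pairing] = []
        for combo in itertools.product(*options):
            g1: Optional[frozenset] = None
            g2: Optional[frozenset] = None
            for (ea, eb) in combo:
                m1, m2 = eag_members[ea], eag_members[eb]
                g1 = m1 if g1 is None else g1 & m1
                g2 = m2 if g2 is None else g2 & m2
            if not g1 or not g2:
                continue
            key = frozenset((g1, g2))
            if key in seen:
                continue
            seen.add(key)
            found.append(
                Pairing(group1=g1, group2=g2, per_exon=dict(zip(exons, combo)))
            )
        return found

    retained = {e: list(r.result_eags) for e, r in usable.items()}
    pairings = enumerate_pairings(retained)
    used_coamp = False
    if not pairings:
        coamps = [
            (exon, eag_id)
            for exon, res in sorted(usable.items())
            for eag_id in res.coamp_eags
        ]
        for exon, eag_id in coamps:
            trial = {e: list(v) for e, v in retained.items()}
            trial[exon] = trial[exon] + [eag_id]
            pairings = enumerate_pairings(trial)
            if pairings:
                used_coamp = True
                flags.add("coamp_rescued")
                break
    if len(pairings) > 1:
        flags.add("exon_shuffling")
    return pairings, flags, ignored, used_coamp


@dataclass(slots=True)
class SuppressedAlleleReport:
    second_allele_reported: bool
    minor_major_ratio: float
    top_eag: Optional[str] = None
    second_eag: Optional[str] = None


def detect_suppressed_allele(
    scores: Sequence[EagScore],
    cfg: Optional[CallingConfig] = None,
) -> SuppressedAlleleReport:
    """Is a genuine second allele present below the dominant one?

    A second surviving EAG with at least max(2% of the top score, 5)
    best-match reads is reported as a real second allele; the minor/major
    read ratio is returned for QC either way.
    """
    cfg = cfg or CallingConfig()
    if not scores:
        return SuppressedAlleleReport(False, 0.0)
    top = scores[0]
    if len(scores) == 1:
        return SuppressedAlleleReport(False, 0.0, top.eag_id)
    second = scores[1]
    ratio = second.n_best / top.n_best if top.n_best else 0.0
    threshold = max(cfg.suppressed_rel * top.n_best, cfg.suppressed_abs)
    return SuppressedAlleleReport(
        second_allele_reported=second.n_best >= threshold,
        minor_major_ratio=ratio,
        top_eag=top.eag_id,
        second_eag=second.eag_id,
    )


def guard_homozygous(
    call: GenotypeCall,
    locus_read_count: int,
    cfg: Optional[CallingConfig] = None,
) -> GenotypeCall:
    """Block homozygous calls with fewer than 100 reads.

    At 20:1 amplification imbalance a suppressed second allele may sit at
    ~5% of the reads; below 100 reads it could fall under the ~5-read
    detection limit, so such homozygotes are never auto-accepted.
    """
    cfg = cfg or CallingConfig()
    if call.zygosity == "homozygous" and locus_read_count < cfg.min_homozygous_reads:
        call.zygosity = "blocked_homozygous"
        call.flags.add("low_reads_homozygous")
    return call


def _ramp(value: float, thresholds: tuple[float, float]) -> float:
    lo, hi = thresholds
    if value >= hi:
        return 1.0
    if value <= lo:
        return 0.0
    return (value - lo) / (hi - lo)


def rate_result(
    metrics: Mapping[str, float],
    cfg: Optional[RatingConfig] = None,
) -> float:
    """Product of two-threshold linear ramps over the rating parameters.

    Each metric scores 1 above its upper threshold, 0 below its lower one
    and linearly in between; the final rating is the product, so any
    failing parameter annihilates it.
    """
    cfg = cfg or RatingConfig()
    rating = 1.0
    for name in ("primer_match", "eag_association", "contributing_reads"):
        value = metrics[name]
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"metric {name}={value} outside [0, 1]")
        rating *= _ramp(value, getattr(cfg, name))
    return rating


def finalize(call: GenotypeCall) -> str:
    """Set the review status from rating, flags and combination outcome.

    Only a rating of exactly 1 with no flags of any kind (and no blocked
    homozygosity) is submitted automatically; unresolved >2-result
    conflicts require editing; anything else goes to analyst review.
    """
    if call.failure_reason or not call.pairings:
        call.status = "failed"
        return call.status
    if "too_many_results" in call.flags:
        call.status = "edit_required"
        return call.status
    if (
        call.rating == 1.0
        and call.zygosity != "blocked_homozygous"
        and not call.flags
    ):
        call.status = "auto"
    else:
        call.status = "review"
    return call.status


def encode_ambiguity(allele_groups: Sequence[frozenset[str]]) -> str:
    """Deterministic ambiguity string: sorted alleles joined by '/', the two
    chromosome groups joined by '+' in canonical order."""
    if not allele_groups or not allele_groups[0]:
        raise ValueError("allele groups must be non-empty")
    groups = ["/".join(sorted(g)) for g in allele_groups]
    groups.sort()
    if len(groups) == 1:
        groups = groups * 2
    return "+".join(groups)
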