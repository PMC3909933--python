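"""Classification of ranked EAGs: result, noise, crossover, co-amplificate,
potential new allele, or discarded.

For one sample, locus and exon, the surviving EAGs are processed in rank
order (by best-match reads).  An EAG below 1/50 of the top score is
discarded outright.  The rest are tested, in fixed precedence, for being

* an off-target PCR product (consensus matches an allele of a different
  locus — ``co_amplificate``);
* a PCR crossover chimera (consensus = prefix of one higher-ranked EAG +
  suffix of another — ``crossover``);
* sequencing noise of a higher-ranked EAG (an exact binomial test on the
  number of reads that Q-value-governed errors would convert — ``noise``);
* a potential new allele (a systematically recurring SNP in the best-match
  read pile);

and anything unexplained remains a ``result``.  More than two results per
exon raises a warning or an error depending on how small the third one is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .matching import EagScore
from .reference import EAG

__all__ = [
    "ClassificationConfig",
    "AlignedRead",
    "ConsensusReport",
    "NoiseTestResult",
    "EagClassification",
    "ClassificationOutcome",
    "build_consensus",
    "detect_new_allele",
    "noise_test",
    "detect_crossover_eag",
    "detect_coamplification",
    "classify_eags",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

LABELS = (
    "result",
    "potential_new_allele",
    "noise",
    "crossover",
    "co_amplificate",
    "discarded",
)


@dataclass(slots=True)
class ClassificationConfig:
    """Knobs of the classification stage.

    ``discard_divisor``: EAGs below top/50 best matches are discarded.
    ``noise_alpha``: a lower EAG is noise when the upper-tail binomial
    p-value of its read count under the error model is ≥ this level (i.e.
    the count is *explainable* as noise).  SNP calling for new-allele
    detection requires an alternate base in ≥ ``snp_fraction`` of covering
    reads, with ≥ ``snp_min_reads`` reads and mean Phred ≥ ``snp_min_q``.
    ``warn_third_fraction``: a third result below this fraction of the top
    result downgrades the >2-results error to a warning.
    """

    discard_divisor: float = 50.0
    noise_alpha: float = 0.01
    snp_fraction: float = 0.8
    snp_min_q: float = 25.0
    snp_min_reads: int = 5
    coamp_max_mismatches: int = 2
    warn_third_fraction: float = 0.2


@dataclass(slots=True)
class AlignedRead:
    """A best-match read placed on the exon coordinate frame.

    Reverse-direction reads are reverse-complemented (and their qualities
    reversed) before alignment, so ``sequence[i]`` sits at exon position
    ``offset + i`` for every read.
    """

    sequence: str
    quals: np.ndarray
    offset: int


@dataclass
class ConsensusReport:
    eag_id: str
    consensus: str
    base_counts: np.ndarray  # (exon_len, 4)
    qual_sums: np.ndarray  # (exon_len, 4)
    coverage: np.ndarray  # (exon_len,)
    uncovered: list[int]
    disagreements: list[int]  # positions where consensus != EAG reference
    n_reads: int


def build_consensus(eag: EAG, reads: Sequence[AlignedRead]) -> ConsensusReport:
    """Majority base call per exon position over the best-match read pile.

    Ties break toward the EAG reference base; zero-coverage positions are
    flagged and filled with the reference base.
    """
    length = len(eag.exon_sequence)
    counts = np.zeros((length, 4), dtype=np.int64)
    qsums = np.zeros((length, 4), dtype=np.float64)
    code = np.full(256, -1, dtype=np.int8)
    for b, j in _BASE_INDEX.items():
        code[ord(b)] = j
    for read in reads:
        lo = max(0, -read.offset)
        hi = min(len(read.sequence), length - read.offset)
        if hi <= lo:
            continue
        seq = np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)[lo:hi]
        idx = code[seq]
        valid = idx >= 0
        pos = np.arange(lo, hi)[valid] + read.offset
        base_idx = idx[valid].astype(np.intp)
        np.add.at(counts, (pos, base_idx), 1)
        np.add.at(qsums, (pos, base_idx), np.asarray(read.quals[lo:hi], dtype=np.float64)[valid])
    coverage = counts.sum(axis=1)
    consensus = list(eag.exon_sequence)
    uncovered: list[int] = []
    disagreements: list[int] = []
    for pos in range(length):
        if coverage[pos] == 0:
            uncovered.append(pos)
            continue
        row = counts[pos]
        top = row.max()
        winners = [b for b, c in zip(_BASES, row) if c == top]
        ref = eag.exon_sequence[pos]
        call = ref if ref in winners else winners[0]
        consensus[pos] = call
        if call != ref:
            disagreements.append(pos)
    return ConsensusReport(
        eag_id=eag.id,
        consensus="".join(consensus),
        base_counts=counts,
        qual_sums=qsums,
        coverage=coverage,
        uncovered=uncovered,
        disagreements=disagreements,
        n_reads=len(reads),
    )


def detect_new_allele(
    report: ConsensusReport,
    eag: EAG,
    cfg: Optional[ClassificationConfig] = None,
) -> Optional[list[tuple[int, str, str]]]:
    """Systematic SNPs in the best-match pile: positions where an alternate
    base is carried by ≥ ``snp_fraction`` of covering reads, with enough
    reads and quality.  Returns ``None`` when nothing qualifies."""
    cfg = cfg or ClassificationConfig()
    if report.n_reads == 0:
        return None
    snps: list[tuple[int, str, str]] = []
    for pos in range(len(report.consensus)):
        cov = report.coverage[pos]
        if cov == 0:
            continue
        ref = eag.exon_sequence[pos]
        for j, base in enumerate(_BASES):
            if base == ref:
                continue
            n_alt = int(report.base_counts[pos, j])
            if n_alt < cfg.snp_min_reads or n_alt < cfg.snp_fraction * cov:
                continue
            mean_q = report.qual_sums[pos, j] / n_alt
            if mean_q >= cfg.snp_min_q:
                snps.append((pos, ref, base))
    return snps or None


@dataclass(slots=True)
class NoiseTestResult:
    low_eag: str
    high_eag: str
    n_low: int
    n_total: int
    p_error_est: float
    p_value: float
    n_discriminating: int
    is_noise: bool


def noise_test(
    low: EagScore,
    high: EagScore,
    low_eag: EAG,
    high_eag: EAG,
    high_reads: Sequence[AlignedRead],
    cfg: Optional[ClassificationConfig] = None,
) -> NoiseTestResult:
    """Can the lower EAG's read count be explained as noise of the higher?

    For every best-match read of the higher EAG, the probability of being
    misread as the lower EAG is the product, over the discriminating
    positions the read covers, of its per-base error probability
    10^(−Q/10).  The mean over reads gives a per-read conversion
    probability p; the upper-tail exact binomial probability of observing
    ≥ n_low conversions among n_low + n_high reads is the p-value.  The low
    EAG is noise when p-value ≥ alpha — its count is unsurprising under the
    error model.
    """
    cfg = cfg or ClassificationConfig()
    seq_lo, seq_hi = low_eag.exon_sequence, high_eag.exon_sequence
    disc = [i for i in range(min(len(seq_lo), len(seq_hi))) if seq_lo[i] != seq_hi[i]]
    if not disc:
        raise ValueError(
            f"EAGs {low_eag.id} and {high_eag.id} are identical over the exon; "
            "noise test inapplicable"
        )
    per_read: list[float] = []
    for read in high_reads:
        prob = 1.0
        for pos in disc:
            i = pos - read.offset
            if 0 <= i < len(read.sequence):
                prob *= 10.0 ** (-float(read.quals[i]) / 10.0)
        per_read.append(prob)
    p_err = float(np.mean(per_read)) if per_read else 0.0
    n_low, n_high = low.n_best, high.n_best
    n_total = n_low + n_high
    # upper tail P(X >= n_low), X ~ Binomial(n_total, p_err)
    p_value = float(stats.binom.sf(n_low - 1, n_total, p_err)) if n_low > 0 else 1.0
    return NoiseTestResult(
        low_eag=low_eag.id,
        high_eag=high_eag.id,
        n_low=n_low,
        n_total=n_total,
        p_error_est=p_err,
        p_value=p_value,
        n_discriminating=len(disc),
        is_noise=p_value >= cfg.noise_alpha,
    )


def detect_crossover_eag(
    candidate: ConsensusReport,
    higher: Sequence[ConsensusReport],
) -> Optional[tuple[int, str, str]]:
    """Single-breakpoint chimera check against higher-ranked EAGs.

    Scans all breakpoints b and ordered pairs (i, j): the candidate is a
    crossover when prefix(i, b) + suffix(j, b) equals its consensus for
    some combination.  Returns the first hit (smallest b, then
    lexicographic pair of ids), or ``None``.
    """
    if len(higher) < 2:
        return None
    cand = candidate.consensus
    n = len(cand)

    def common_prefix(a: str, b: str) -> int:
        m = min(len(a), len(b))
        for k in range(m):
            if a[k] != b[k]:
                return k
        return m

    def common_suffix(a: str, b: str) -> int:
        m = min(len(a), len(b))
        for k in range(m):
            if a[-1 - k] != b[-1 - k]:
                return k
        return m

    hits: list[tuple[int, str, str]] = []
    ordered = sorted(higher, key=lambda r: r.eag_id)
    for i_rep in ordered:
        if len(i_rep.consensus) != n:
            continue
        lcp = common_prefix(cand, i_rep.consensus)
        for j_rep in ordered:
            if j_rep.eag_id == i_rep.eag_id or len(j_rep.consensus) != n:
                continue
            lcs = common_suffix(cand, j_rep.consensus)
            if lcp + lcs >= n:
                hits.append((max(0, n - lcs), i_rep.eag_id, j_rep.eag_id))
    if not hits:
        return None
    return min(hits)


def detect_coamplification(
    report: ConsensusReport,
    alleles: Mapping[str, "object"],
    target_locus: str,
    cfg: Optional[ClassificationConfig] = None,
    exon: Optional[int] = None,
) -> Optional[tuple[str, str, int]]:
    """Match the consensus against the whole reference to spot off-target
    products (paralogs co-amplified by the target primers).

    A hit to an allele of a *different* locus with ≤ 2 mismatches — and
    strictly fewer mismatches than the best same-locus allele — marks the
    EAG as a co-amplificate.  Returns (locus, allele_name, mismatches).
    """
    cfg = cfg or ClassificationConfig()
    cand = report.consensus
    best_other: Optional[tuple[int, str, str]] = None
    best_same = None
    for name, allele in alleles.items():
        exons = allele.exon_seqs if exon is None else {exon: allele.exon_seqs.get(exon)}
        for ex, seq in exons.items():
            if seq is None or abs(len(seq) - len(cand)) > cfg.coamp_max_mismatches:
                continue
            m = min(len(seq), len(cand))
            mm = sum(1 for k in range(m) if seq[k] != cand[k]) + abs(len(seq) - m) + (
                len(cand) - m
            )
            if allele.locus == target_locus:
                if best_same is None or mm < best_same:
                    best_same = mm
            else:
                key = (mm, allele.locus, name)
                if best_other is None or key < best_other:
                    best_other = key
    if best_other is None:
        return None
    mm, locus, name = best_other
    if mm <= cfg.coamp_max_mismatches and (best_same is None or mm < best_same):
        return (locus, name, mm)
    return None


@dataclass
class EagClassification:
    eag_id: str
    rank: int
    n_best: int
    label: str
    evidence: dict = field(default_factory=dict)


@dataclass
class ClassificationOutcome:
    classifications: list[EagClassification]
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    def result_eags(self) -> list[EagClassification]:
        return [c for c in self.classifications if c.label == "result"]

    def with_label(self, label: str) -> list[EagClassification]:
        return [c for c in self.classifications if c.label == label]


def classify_eags(
    scored: Sequence[EagScore],
    eag_reads: Mapping[str, Sequence[AlignedRead]],
    eag_by_id: Mapping[str, EAG],
    alleles: Mapping[str, "object"],
    target_locus: str,
    exon: int,
    cfg: Optional[ClassificationConfig] = None,
) -> ClassificationOutcome:
    """Label every ranked EAG of one sample-locus-exon.

    Precedence per EAG, top-down: 1/50 discard → co-amplificate →
    crossover → noise → potential new allele → result.  Artifacts are
    excluded before novelty claims.  With more than two results, a warning
    is emitted when the third-ranked result is small (< 20% of the top
    result), an error otherwise.
    """
    cfg = cfg or ClassificationConfig()
    out = ClassificationOutcome(classifications=[])
    if not scored:
        return out
    top_best = scored[0].n_best
    consensus_cache: dict[str, ConsensusReport] = {}
    surviving_reports: list[ConsensusReport] = []
    labeled: list[tuple[EagScore, EagClassification]] = []

    for rank, score in enumerate(scored):
        eag = eag_by_id[score.eag_id]
        cls = EagClassification(score.eag_id, rank, score.n_best, "result")
        if score.n_best < top_best / cfg.discard_divisor:
            cls.label = "discarded"
            cls.evidence["reason"] = f"n_best {score.n_best} < top/{cfg.discard_divisor:g}"
            out.classifications.append(cls)
            labeled.append((score, cls))
            continue
        reads = eag_reads.get(score.eag_id, ())
        report = build_consensus(eag, reads)
        consensus_cache[score.eag_id] = report

        coamp = detect_coamplification(report, alleles, target_locus, cfg, exon=exon)
        if coamp is not None:
            cls.label = "co_amplificate"
            cls.evidence["off_target"] = {"locus": coamp[0], "allele": coamp[1], "mismatches": coamp[2]}
        else:
            xover = detect_crossover_eag(report, surviving_reports)
            if xover is not None:
                cls.label = "crossover"
                cls.evidence["breakpoint"] = xover[0]
                cls.evidence["parents"] = (xover[1], xover[2])
            else:
                noise_hit = None
                for prev_score, prev_cls in labeled:
                    if prev_cls.label not in ("result", "potential_new_allele"):
                        continue
                    try:
                        test = noise_test(
                            score,
                            prev_score,
                            eag,
                            eag_by_id[prev_score.eag_id],
                            eag_reads.get(prev_score.eag_id, ()),
                            cfg,
                        )
                    except ValueError:
                        continue
                    if test.is_noise:
                        noise_hit = test
                        break
                if noise_hit is not None:
                    cls.label = "noise"
                    cls.evidence["p_value"] = noise_hit.p_value
                    cls.evidence["p_error_est"] = noise_hit.p_error_est
                    cls.evidence["of_eag"] = noise_hit.high_eag
                else:
                    snps = detect_new_allele(report, eag, cfg)
                    if snps is not None:
                        cls.label = "potential_new_allele"
                        cls.evidence["snps"] = snps
        if cls.label != "discarded":
            surviving_reports.append(report)
        out.classifications.append(cls)
        labeled.append((score, cls))

    results = out.result_eags()
    if len(results) > 2:
        third = results[2]
        top_result = results[0]
        msg = (
            f"{len(results)} result EAGs for {target_locus} exon {exon}; "
            f"third has {third.n_best}/{top_result.n_best} best matches"
        )
        if third.n_best < cfg.warn_third_fraction * top_result.n_best:
            out.warnings.append(msg)
        else:
            out.errors.append(msg)
    return out
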