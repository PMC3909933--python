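"""End-to-end typing: demultiplexed reads → rated genotype calls.

Per sample, every read is routed by primer recognition to its locus, exon
and direction, matched against the PEAG trees, and accumulated into
per-EAG evidence.  Per locus-exon the ranked EAGs are classified, the two
top results per exon are combined across exons into ambiguity-coded
genotype candidates, safeguards (exon read minimum, homozygous block,
suppressed-allele rule) are applied, the call is rated, and a review
status is assigned.  Analyst decisions enter as a non-interactive override
table (include / exclude / ignore-artifact per EAG) which triggers
recombination and re-rating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calling import (
    CallingConfig,
    ExonResult,
    GenotypeCall,
    combine_exons,
    detect_suppressed_allele,
    finalize,
    guard_homozygous,
    rate_result,
)
from .classify import (
    AlignedRead,
    ClassificationConfig,
    ClassificationOutcome,
    classify_eags,
)
from .matching import (
    MIN_BEST_MATCH_READS,
    assign_read,
    match_read_to_peags,
    score_eags,
)
from .primers import PrimerRecognizer, RecognitionConfig, clip_primer
from .readio import DemuxResult, QualityRead, SampleSheet, demultiplex
from .reference import ReferenceModel, reverse_complement

__all__ = [
    "TypingConfig",
    "Overrides",
    "SampleLocusDetail",
    "TypingRunResult",
    "type_sample",
    "run_typing",
]


@dataclass
class TypingConfig:
    recognition: RecognitionConfig = field(default_factory=RecognitionConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    min_best: int = MIN_BEST_MATCH_READS


@dataclass
class Overrides:
    """Analyst decisions: per sample-locus-exon EAG include/exclude, plus a
    run-level list of EAG ids to ignore as known artifacts in any sample."""

    include: set[tuple[str, str, int, str]] = field(default_factory=set)
    exclude: set[tuple[str, str, int, str]] = field(default_factory=set)
    ignore_artifacts: set[str] = field(default_factory=set)

    @classmethod
    def from_tsv(cls, path) -> "Overrides":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "locus": str, "exon": int})
        ov = cls()
        for r in df.itertuples(index=False):
            key = (r.sample, r.locus, int(r.exon), r.eag_id)
            if r.action == "include":
                ov.include.add(key)
            elif r.action == "exclude":
                ov.exclude.add(key)
            elif r.action == "ignore_artifact":
                ov.ignore_artifacts.add(r.eag_id)
            else:
                raise ValueError(f"unknown override action '{r.action}'")
        return ov


@dataclass
class SampleLocusDetail:
    call: GenotypeCall
    outcomes: dict[int, ClassificationOutcome]
    exon_results: dict[int, ExonResult]
    suppressed: dict[int, object]


def _aligned(
    insert: QualityRead, direction: str, exon_len: int
) -> AlignedRead:
    """Place a primer-clipped read on the exon coordinate frame."""
    if direction == "forward":
        return AlignedRead(insert.sequence, insert.quals, 0)
    seq = reverse_complement(insert.sequence)
    quals = insert.quals[::-1]
    return AlignedRead(seq, quals, exon_len - len(seq))


def type_sample(
    sample_id: str,
    pairs: Iterable[tuple[QualityRead, QualityRead]],
    reference: ReferenceModel,
    cfg: Optional[TypingConfig] = None,
    recognizer: Optional[PrimerRecognizer] = None,
    overrides: Optional[Overrides] = None,
    match_cache: Optional[dict] = None,
) -> dict[str, SampleLocusDetail]:
    """Type one sample's read pairs at every locus of the reference.

    Forward and reverse mates are matched independently against their
    direction's PEAG trees; mate identity is kept only for bookkeeping.
    """
    cfg = cfg or TypingConfig()
    overrides = overrides or Overrides()
    if recognizer is None:
        recognizer = PrimerRecognizer(
            reference.primers, reference.primer_tree, cfg.recognition
        )
    cache = match_cache if match_cache is not None else {}

    n_reads = 0
    n_primer_matched = 0
    per_exon_assignments: dict[tuple[str, int], list] = {}
    per_exon_reads: dict[tuple[str, int], int] = {}
    eag_reads: dict[tuple[str, int], dict[str, list[AlignedRead]]] = {}

    for pair in pairs:
        for read in pair:
            n_reads += 1
            pm = recognizer.recognize(read)
            if not pm.matched:
                continue
            n_primer_matched += 1
            primer = recognizer.primer_by_id[pm.primer_id]
            key = (primer.locus, primer.exon)
            tree = reference.peag_trees.get((primer.locus, primer.exon, primer.direction))
            if tree is None:
                continue
            insert = clip_primer(read, pm)
            per_exon_reads[key] = per_exon_reads.get(key, 0) + 1
            ckey = (
                primer.locus,
                primer.exon,
                primer.direction,
                insert.sequence,
                insert.quals.tobytes(),
            )
            cands = cache.get(ckey)
            if cands is None:
                cands = match_read_to_peags(insert, tree, cfg.recognition)
                cache[ckey] = cands
            assignment = assign_read(
                cands, reference.peag_members, read.read_id, primer.direction
            )
            per_exon_assignments.setdefault(key, []).append(assignment)
            if assignment.best:
                exon_len = reference.exon_length(primer.locus, primer.exon)
                aligned = _aligned(insert, primer.direction, exon_len)
                bucket = eag_reads.setdefault(key, {})
                for eag_id in assignment.best:
                    bucket.setdefault(eag_id, []).append(aligned)

    primer_fraction = n_primer_matched / n_reads if n_reads else 0.0

    details: dict[str, SampleLocusDetail] = {}
    target_loci = sorted(
        {locus for locus, _ in per_exon_assignments} | set(reference.loci)
    )
    for locus in target_loci:
        exons = sorted(e for (l, e) in reference.eags if l == locus)
        if not exons:
            continue
        has_primers = any(p.locus == locus for p in reference.primers)
        if not has_primers:
            continue  # off-target locus: reference content only, never typed
        outcomes: dict[int, ClassificationOutcome] = {}
        exon_results: dict[int, ExonResult] = {}
        suppressed: dict[int, object] = {}
        n_assoc = 0
        n_routed = 0
        n_contributing = 0
        for exon in exons:
            key = (locus, exon)
            assignments = per_exon_assignments.get(key, [])
            n_routed += per_exon_reads.get(key, 0)
            n_assoc += sum(1 for a in assignments if a.assigned)
            scores = score_eags(assignments, cfg.min_best)
            scores = [
                s for s in scores if s.eag_id not in overrides.ignore_artifacts
            ]
            outcome = classify_eags(
                scores,
                eag_reads.get(key, {}),
                reference.eag_by_id,
                reference.alleles,
                locus,
                exon,
                cfg.classification,
            )
            for cls in outcome.classifications:
                okey = (sample_id, locus, exon, cls.eag_id)
                if okey in overrides.exclude:
                    cls.label = "discarded"
                    cls.evidence["override"] = "exclude"
                elif okey in overrides.include:
                    cls.label = "result"
                    cls.evidence["override"] = "include"
            outcomes[exon] = outcome
            suppressed[exon] = detect_suppressed_allele(scores, cfg.calling)
            results = outcome.result_eags()
            coamps = outcome.with_label("co_amplificate")
            total_result_reads = sum(c.n_best for c in results)
            n_contributing += sum(c.n_best for c in results[:2])
            exon_results[exon] = ExonResult(
                locus=locus,
                exon=exon,
                result_eags=[c.eag_id for c in results[:2]],
                coamp_eags=[c.eag_id for c in coamps],
                total_result_reads=total_result_reads,
                warnings=list(outcome.warnings),
                errors=list(outcome.errors),
            )

        pairings, flags, ignored, used_coamp = combine_exons(
            exon_results, reference.eag_members, cfg.calling
        )
        if used_coamp:
            flags.add("coamp_rescued")
        if any(r.errors for r in exon_results.values()):
            flags.add("too_many_results")
        if any(r.warnings for r in exon_results.values()):
            flags.add("extra_result_warning")

        if pairings:
            primary = pairings[0]
            zygosity = "homozygous" if primary.homozygous else "heterozygous"
            call = GenotypeCall(
                sample=sample_id,
                locus=locus,
                allele_groups=(primary.group1, primary.group2),
                zygosity=zygosity,
                pairings=pairings,
                flags=flags,
                ignored_exons=ignored,
            )
        else:
            call = GenotypeCall(
                sample=sample_id,
                locus=locus,
                allele_groups=(frozenset(), frozenset()),
                zygosity="heterozygous",
                pairings=[],
                flags=flags,
                failure_reason="low_reads" if "low_reads" in flags else "no_consistent_pairing",
                ignored_exons=ignored,
            )

        locus_read_count = sum(
            r.total_result_reads
            for e, r in exon_results.items()
            if e not in ignored
        )
        if locus_read_count < cfg.calling.min_homozygous_reads:
            call.flags.add("low_reads")
        call = guard_homozygous(call, locus_read_count, cfg.calling)
        if call.zygosity == "homozygous" or call.zygosity == "blocked_homozygous":
            for exon, rep in suppressed.items():
                if rep.second_allele_reported:
                    call.flags.add("suppressed_allele_suspected")

        metrics = {
            "primer_match": primer_fraction,
            "eag_association": min(1.0, n_assoc / n_routed) if n_routed else 0.0,
            "contributing_reads": min(1.0, n_contributing / n_routed) if n_routed else 0.0,
        }
        call.metrics = metrics
        call.rating = rate_result(metrics, cfg.calling.rating) if pairings else 0.0
        finalize(call)
        details[locus] = SampleLocusDetail(
            call=call,
            outcomes=outcomes,
            exon_results=exon_results,
            suppressed=suppressed,
        )
    return details


@dataclass
class TypingRunResult:
    calls: dict[tuple[str, str], GenotypeCall]
    details: dict[tuple[str, str], SampleLocusDetail]
    demux: DemuxResult

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for (sample, locus), call in sorted(self.calls.items()):
            rows.append(
                {
                    "sample": sample,
                    "locus": locus,
                    "genotype": call.genotype_string,
                    "zygosity": call.zygosity,
                    "rating": call.rating,
                    "status": call.status,
                    "flags": ",".join(sorted(call.flags)),
                }
            )
        return pd.DataFrame(rows)

    def classification_frame(self) -> pd.DataFrame:
        rows = []
        for (sample, locus), detail in sorted(self.details.items()):
            for exon, outcome in sorted(detail.outcomes.items()):
                for cls in outcome.classifications:
                    rows.append(
                        {
                            "sample": sample,
                            "locus": locus,
                            "exon": exon,
                            "eag_id": cls.eag_id,
                            "rank": cls.rank,
                            "n_best": cls.n_best,
                            "label": cls.label,
                            "detail": repr(cls.evidence) if cls.evidence else "",
                        }
                    )
        return pd.DataFrame(rows)


def run_typing(
    reference: ReferenceModel,
    pairs: Iterable[tuple[QualityRead, QualityRead]],
    samplesheet: SampleSheet,
    cfg: Optional[TypingConfig] = None,
    index1_pool: Optional[Sequence[str]] = None,
    index2_pool: Optional[Sequence[str]] = None,
    overrides: Optional[Overrides] = None,
) -> TypingRunResult:
    """Demultiplex a run and type every sample at every targeted locus."""
    cfg = cfg or TypingConfig()
    demux = demultiplex(pairs, samplesheet, index1_pool, index2_pool)
    recognizer = PrimerRecognizer(
        reference.primers, reference.primer_tree, cfg.recognition
    )
    cache: dict = {}
    calls: dict[tuple[str, str], GenotypeCall] = {}
    details: dict[tuple[str, str], SampleLocusDetail] = {}
    for sample_id, sample_pairs in sorted(demux.by_sample.items()):
        if not sample_pairs:
            continue
        sample_details = type_sample(
            sample_id,
            sample_pairs,
            reference,
            cfg,
            recognizer=recognizer,
            overrides=overrides,
            match_cache=cache,
        )
        for locus, detail in sample_details.items():
            calls[(sample_id, locus)] = detail.call
            details[(sample_id, locus)] = detail
    return TypingRunResult(calls=calls, details=details, demux=demux)
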