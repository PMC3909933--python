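"""Synthetic reference databases, samples and amplicon reads with ground truth.

The simulator emulates the data-generating process of short-amplicon HLA
typing: per locus an ancestral exon (~270 bp) with intronic flanks, alleles
derived by seeded substitutions, primers sitting in the introns so that
every read begins with its target-specific primer, diploid amplicons with
allelic imbalance up to 20:1, per-cycle Phred profiles whose emitted Q
values are calibrated (per-base error probability 10^(−Q/10)),
single-breakpoint PCR crossover chimeras, optional co-amplification of an
off-target paralog, and a 96×16 dual-index space of which a run uses only
a fraction.  Every emitted read is traceable to a ground-truth record.

The error model is substitution-only: intronic reference indels are the
matcher's concern, read indels are not simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .readio import QualityRead, SampleSheet, write_paired_fastq
from .reference import (
    AlleleSequence,
    PrimerDef,
    reverse_complement,
    write_primer_library,
    write_reference,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ReadTruth",
    "SimulatedReference",
    "SimulatedRun",
    "simulate_reference",
    "simulate_sample_reads",
    "inject_crossover",
    "simulate_run",
    "validation_pair_reference",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort.

    Defaults mirror the regimes of routine amplicon HLA typing: 251-cycle
    paired-end reads over ~270 bp exons 2 and 3, on the order of 1000 read
    pairs per amplicon, a crossover-chimera fraction in the tens of
    percent, and a 96×16 dual-index space.  ``error_rate`` set to a float
    emits a flat quality profile at the matching Phred score; left as
    ``None`` the per-cycle profile (mean ``q_mean`` declining by
    ``q_decline`` over the read, ± ``q_spread``) applies.
    """

    seed: int = 0
    n_loci: int = 3
    alleles_per_locus: int = 12
    pairwise_divergence: int = 8  # substitutions per exon vs the locus ancestor
    exon_length: int = 270
    flank_length: int = 60
    primer_length: int = 22
    read_length: int = 251
    depth: int = 1000  # read pairs per amplicon (locus-exon)
    imbalance_ratio: float = 1.0  # major:minor amplification, up to ~20
    crossover_rate: float = 0.15
    coamp_rate: float = 0.0
    error_rate: Optional[float] = None
    q_mean: float = 33.0
    q_spread: float = 3.0
    q_decline: float = 6.0
    index1_count: int = 96
    index2_count: int = 16
    exons: tuple[int, ...] = (2, 3)
    paralog_divergence: int = 1

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "coamp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.error_rate is not None and not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.imbalance_ratio < 1.0:
            raise ValueError("imbalance_ratio is major:minor and must be ≥ 1")
        if self.pairwise_divergence >= self.exon_length // 4:
            raise ValueError("divergence too high for a conserved-primer locus")


@dataclass(slots=True)
class ReadTruth:
    sample: str
    locus: str
    exon: int
    source: str  # allele name, or "chimera"
    prefix_allele: str = ""
    suffix_allele: str = ""
    breakpoint: int = -1  # exon coordinate of the template switch
    n_errors_r1: int = 0
    n_errors_r2: int = 0
    hopped: bool = False
    coamplified: bool = False


@dataclass
class GroundTruth:
    """Per-read and per-sample truth for a simulated data set."""

    genotypes: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    imbalance: dict[tuple[str, str], float] = field(default_factory=dict)
    reads: dict[str, ReadTruth] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        rows = [{"read_id": rid, **asdict(rt)} for rid, rt in self.reads.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedReference:
    alleles: list[AlleleSequence]
    primers: list[PrimerDef]
    index1: list[str]
    index2: list[str]
    exon_partition: dict[tuple[str, int], list[frozenset[str]]]
    paralog_of: dict[str, str] = field(default_factory=dict)  # target locus -> paralog allele
    target_loci: list[str] = field(default_factory=list)

    def allele(self, name: str) -> AlleleSequence:
        return self._by_name[name]

    def __post_init__(self) -> None:
        self._by_name = {a.name: a for a in self.alleles}

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "reference.fasta",
            "exons": outdir / "exons.tsv",
            "primers": outdir / "primers.tsv",
        }
        write_reference(self.alleles, paths["fasta"], paths["exons"])
        write_primer_library(self.primers, paths["primers"])
        return paths


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _substitute(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for pos in positions:
        old = arr[pos]
        choices = _BASES[_BASES != old]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_reference(cfg: SimulationConfig) -> SimulatedReference:
    """Build a seeded allele reference + primer library + index sets.

    Per locus: an ancestral exon per typed exon with conserved intronic
    flanks; alleles derive from the ancestor by ``pairwise_divergence``
    random substitutions.  Forward primers are the last ``primer_length``
    bases of the 5' flank and reverse primers the reverse complement of
    the first bases of the 3' flank, so primer-clipped reads enter the
    exon at its boundary.  With ``coamp_rate`` > 0 each locus also gets an
    off-target paralog sharing the primer sites at reduced exon identity.
    """
    rng = np.random.default_rng(cfg.seed)
    alleles: list[AlleleSequence] = []
    primers: list[PrimerDef] = []
    partition: dict[tuple[str, int], list[frozenset[str]]] = {}
    paralog_of: dict[str, str] = {}
    target_loci: list[str] = []

    for li in range(cfg.n_loci):
        locus = f"LOC{li + 1}"
        target_loci.append(locus)
        ancestors: dict[int, str] = {}
        flank5: dict[int, str] = {}
        flank3: dict[int, str] = {}
        for exon in cfg.exons:
            ancestors[exon] = _random_dna(rng, cfg.exon_length)
            flank5[exon] = _random_dna(rng, cfg.flank_length)
            flank3[exon] = _random_dna(rng, cfg.flank_length)
            primers.append(
                PrimerDef(
                    id=f"{locus}_e{exon}_F",
                    locus=locus,
                    exon=exon,
                    direction="forward",
                    sequence=flank5[exon][-cfg.primer_length :],
                )
            )
            primers.append(
                PrimerDef(
                    id=f"{locus}_e{exon}_R",
                    locus=locus,
                    exon=exon,
                    direction="reverse",
                    sequence=reverse_complement(flank3[exon][: cfg.primer_length]),
                )
            )
        for k in range(cfg.alleles_per_locus):
            name = f"{locus}*{k // 10 + 1:02d}:{k % 10 + 1:02d}"
            exon_seqs = {}
            for exon in cfg.exons:
                if k == 0:
                    exon_seqs[exon] = ancestors[exon]
                else:
                    positions = rng.choice(
                        cfg.exon_length, size=cfg.pairwise_divergence, replace=False
                    )
                    exon_seqs[exon] = _substitute(ancestors[exon], positions, rng)
            flanks = {}
            for exon in cfg.exons:
                flanks[(exon, "5p")] = flank5[exon]
                flanks[(exon, "3p")] = flank3[exon]
            alleles.append(AlleleSequence(name, locus, exon_seqs, flanks))
        if cfg.coamp_rate > 0:
            # paralog amplified by the same primers, 1–2 substitutions away
            pl = f"{locus}H"
            pname = f"{pl}*01:01"
            exon_seqs = {}
            for exon in cfg.exons:
                mid = cfg.exon_length // 2
                positions = [mid + 7 * j for j in range(cfg.paralog_divergence)]
                exon_seqs[exon] = _substitute(ancestors[exon], positions, rng)
            flanks = {}
            for exon in cfg.exons:
                flanks[(exon, "5p")] = flank5[exon]
                flanks[(exon, "3p")] = flank3[exon]
            alleles.append(AlleleSequence(pname, pl, exon_seqs, flanks))
            paralog_of[locus] = pname

    for locus in {a.locus for a in alleles}:
        for exon in cfg.exons:
            groups: dict[str, set[str]] = {}
            for a in alleles:
                if a.locus == locus:
                    groups.setdefault(a.exon_seqs[exon], set()).add(a.name)
            partition[(locus, exon)] = sorted(
                (frozenset(g) for g in groups.values()), key=min
            )

    index1 = [_random_dna(rng, 8) for _ in range(cfg.index1_count)]
    index2 = [_random_dna(rng, 8) for _ in range(cfg.index2_count)]
    # index sequences must be unique within each list
    while len(set(index1)) < len(index1):
        index1 = [_random_dna(rng, 8) for _ in range(cfg.index1_count)]
    while len(set(index2)) < len(index2):
        index2 = [_random_dna(rng, 8) for _ in range(cfg.index2_count)]

    return SimulatedReference(
        alleles=alleles,
        primers=primers,
        index1=index1,
        index2=index2,
        exon_partition=partition,
        paralog_of=paralog_of,
        target_loci=target_loci,
    )


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

def _quality_matrix(
    n: int, length: int, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    if cfg.error_rate is not None:
        if cfg.error_rate <= 0:
            return np.full((n, length), 41, dtype=np.uint8)
        q = int(round(-10.0 * np.log10(cfg.error_rate)))
        return np.full((n, length), np.clip(q, 2, 41), dtype=np.uint8)
    cycle = np.arange(length)
    mean = cfg.q_mean - cfg.q_decline * cycle / max(length - 1, 1)
    noise = rng.uniform(-cfg.q_spread, cfg.q_spread, size=(n, length))
    return np.clip(np.rint(mean[None, :] + noise), 2, 41).astype(np.uint8)


def _emit_batch(
    template: str,
    n: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[str], list[np.ndarray], np.ndarray]:
    """n reads from one template: calibrated Q values, seeded substitutions.

    Per base, the error probability is exactly 10^(−Q/10) of the emitted
    Phred score; an erroneous base is replaced by a uniformly chosen other
    base.  Returns sequences, quality arrays and per-read error counts.
    """
    length = len(template)
    quals = _quality_matrix(n, length, cfg, rng)
    if cfg.error_rate is not None and cfg.error_rate <= 0.0:
        # idealized error-free mode: qualities are emitted but never "fire"
        mask = np.zeros((n, length), dtype=bool)
    else:
        p_err = 10.0 ** (-quals.astype(np.float64) / 10.0)
        mask = rng.random((n, length)) < p_err
    base = np.frombuffer(template.encode(), dtype=np.uint8)
    arr = np.tile(base, (n, 1))
    n_err = mask.sum(axis=1)
    if mask.any():
        # substitute with one of the three other bases, uniformly
        idx = np.nonzero(mask)
        shift = rng.integers(1, 4, size=idx[0].size)
        cur = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(cur + shift) % 4]
    seqs = [row.tobytes().decode("ascii") for row in arr]
    qlist = [quals[i] for i in range(n)]
    return seqs, qlist, n_err


def _templates(
    allele: AlleleSequence, exon: int, cfg: SimulationConfig
) -> tuple[str, str]:
    """Forward and reverse read templates (primer + insert) for one amplicon."""
    f5 = allele.flank_seqs[(exon, "5p")]
    f3 = allele.flank_seqs[(exon, "3p")]
    exon_seq = allele.exon_seqs[exon]
    fwd = (f5[-cfg.primer_length :] + exon_seq + f3)[: cfg.read_length]
    rev = (
        reverse_complement(f3[: cfg.primer_length])
        + reverse_complement(f5 + exon_seq)
    )[: cfg.read_length]
    return fwd, rev


def _chimera_templates(
    a1: AlleleSequence, a2: AlleleSequence, exon: int, bp: int, cfg: SimulationConfig
) -> tuple[str, str]:
    """Templates of a single-breakpoint chimera: exon prefix of a1 + suffix of a2."""
    chim = AlleleSequence(
        name=a1.name,
        locus=a1.locus,
        exon_seqs={exon: a1.exon_seqs[exon][:bp] + a2.exon_seqs[exon][bp:]},
        flank_seqs={
            (exon, "5p"): a1.flank_seqs[(exon, "5p")],
            (exon, "3p"): a2.flank_seqs[(exon, "3p")],
        },
    )
    return _templates(chim, exon, cfg)


def simulate_sample_reads(
    sample_id: str,
    genotype: Mapping[str, tuple[str, str]],
    reference: SimulatedReference,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[GroundTruth] = None,
    index_pair: tuple[str, str] = ("", ""),
    serial_start: int = 0,
    imbalance: Optional[Mapping[str, float]] = None,
) -> tuple[list[tuple[QualityRead, QualityRead]], GroundTruth, int]:
    """Emit paired reads for one sample: per amplicon ``depth`` pairs split
    between the two alleles at the imbalance ratio, with crossover chimeras
    injected at ``crossover_rate`` and off-target paralog molecules at
    ``coamp_rate``.  Returns (pairs, truth, next_serial)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    truth = truth if truth is not None else GroundTruth()
    i1, i2 = index_pair
    serial = serial_start
    pairs: list[tuple[QualityRead, QualityRead]] = []

    for locus, (a1_name, a2_name) in sorted(genotype.items()):
        truth.genotypes[(sample_id, locus)] = (a1_name, a2_name)
        ratio = (imbalance or {}).get(locus, cfg.imbalance_ratio)
        truth.imbalance[(sample_id, locus)] = ratio
        a1 = reference.allele(a1_name)
        a2 = reference.allele(a2_name)
        paralog = reference.paralog_of.get(locus)
        for exon in cfg.exons:
            n_total = cfg.depth
            n_coamp = (
                rng.binomial(n_total, cfg.coamp_rate) if paralog and cfg.coamp_rate else 0
            )
            n_target = n_total - n_coamp
            p1 = ratio / (1.0 + ratio)
            n1 = int(rng.binomial(n_target, p1)) if a1_name != a2_name else n_target
            batches: list[tuple[str, int]] = [(a1_name, n1)]
            if a1_name != a2_name:
                batches.append((a2_name, n_target - n1))
            if n_coamp:
                batches.append((paralog, n_coamp))
            for source_name, count in batches:
                if count <= 0:
                    continue
                allele = reference.allele(source_name)
                tf, tr = _templates(allele, exon, cfg)
                sf, qf, ef = _emit_batch(tf, count, cfg, rng)
                sr, qr, er = _emit_batch(tr, count, cfg, rng)
                for i in range(count):
                    rid = f"{sample_id}.{serial:07d}"
                    serial += 1
                    pairs.append(
                        (
                            QualityRead(rid, 1, sf[i], qf[i], i1, i2),
                            QualityRead(rid, 2, sr[i], qr[i], i1, i2),
                        )
                    )
                    truth.reads[rid] = ReadTruth(
                        sample=sample_id,
                        locus=locus,
                        exon=exon,
                        source=source_name,
                        n_errors_r1=int(ef[i]),
                        n_errors_r2=int(er[i]),
                        coamplified=(source_name == paralog),
                    )
    if cfg.crossover_rate > 0:
        pairs = inject_crossover(
            pairs, truth, reference, cfg, rate=cfg.crossover_rate, rng=rng
        )
    return pairs, truth, serial


def inject_crossover(
    pairs: list[tuple[QualityRead, QualityRead]],
    truth: GroundTruth,
    reference: SimulatedReference,
    cfg: SimulationConfig,
    rate: float,
    rng: Optional[np.random.Generator] = None,
    breakpoint: Optional[int] = None,
) -> list[tuple[QualityRead, QualityRead]]:
    """Replace a seeded fraction of heterozygous-sample reads by chimeras.

    Each selected pair is regenerated from a single-breakpoint chimeric
    amplicon (breakpoint uniform over the exon unless fixed); the error
    model is re-applied and the truth record updated with the breakpoint.
    Pairs from homozygous sample-loci are left untouched (chimeras between
    identical templates are undefined) with a warning.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if rate <= 0:
        return pairs
    out: list[tuple[QualityRead, QualityRead]] = []
    any_heterozygous = False
    for r1, r2 in pairs:
        rt = truth.reads[r1.read_id]
        g1, g2 = truth.genotypes[(rt.sample, rt.locus)]
        if g1 != g2:
            any_heterozygous = True
        if rt.coamplified or rng.random() >= rate:
            out.append((r1, r2))
            continue
        if g1 == g2:
            out.append((r1, r2))
            continue
        # prefix from the molecule's own source allele, suffix from the other
        pre = rt.source if rt.source in (g1, g2) else g1
        suf = g2 if pre == g1 else g1
        bp = (
            breakpoint
            if breakpoint is not None
            else int(rng.integers(1, cfg.exon_length))
        )
        tf, tr = _chimera_templates(
            reference.allele(pre), reference.allele(suf), rt.exon, bp, cfg
        )
        (sf,), (qf,), (ef,) = _emit_batch(tf, 1, cfg, rng)
        (sr,), (qr,), (er,) = _emit_batch(tr, 1, cfg, rng)
        out.append(
            (
                QualityRead(r1.read_id, 1, sf, qf, r1.index1, r1.index2),
                QualityRead(r2.read_id, 2, sr, qr, r2.index1, r2.index2),
            )
        )
        truth.reads[r1.read_id] = ReadTruth(
            sample=rt.sample,
            locus=rt.locus,
            exon=rt.exon,
            source="chimera",
            prefix_allele=pre,
            suffix_allele=suf,
            breakpoint=bp,
            n_errors_r1=int(ef),
            n_errors_r2=int(er),
        )
    if pairs and not any_heterozygous:
        warnings.warn(
            "all input pairs come from homozygous sample-loci; "
            "crossover injection is a no-op (chimeras undefined)"
        )
    return out


def validation_pair_reference(
    cfg: SimulationConfig, n_internal: int = 12
) -> SimulatedReference:
    """One-locus, two-allele reference for primer-set validation panels.

    QC panels are chosen to be maximally informative: the two alleles
    differ at positions spread over the whole amplicon *including the
    extreme ends of the insert*, so that a template switch anywhere leaves
    at least two discriminating bases on each side and essentially every
    crossover molecule is detectable.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.exon_length
    positions = [0, 1, 2] + [
        int(round(x)) for x in np.linspace(10, L - 10, n_internal)
    ] + [L - 3, L - 2, L - 1]
    positions = sorted(set(positions))
    locus = "LOC1"
    exon = cfg.exons[0]
    ancestor = _random_dna(rng, L)
    f5 = _random_dna(rng, cfg.flank_length)
    f3 = _random_dna(rng, cfg.flank_length)
    flanks = {(exon, "5p"): f5, (exon, "3p"): f3}
    a1 = AlleleSequence(f"{locus}*01:01", locus, {exon: ancestor}, dict(flanks))
    a2 = AlleleSequence(
        f"{locus}*02:01",
        locus,
        {exon: _substitute(ancestor, positions, rng)},
        dict(flanks),
    )
    primers = [
        PrimerDef(f"{locus}_e{exon}_F", locus, exon, "forward", f5[-cfg.primer_length :]),
        PrimerDef(
            f"{locus}_e{exon}_R",
            locus,
            exon,
            "reverse",
            reverse_complement(f3[: cfg.primer_length]),
        ),
    ]
    return SimulatedReference(
        alleles=[a1, a2],
        primers=primers,
        index1=[_random_dna(rng, 8)],
        index2=[_random_dna(rng, 8)],
        exon_partition={(locus, exon): [frozenset({a1.name}), frozenset({a2.name})]},
        target_loci=[locus],
    )


# ---------------------------------------------------------------------------
# whole runs
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRun:
    reference: SimulatedReference
    samplesheet: SampleSheet
    pairs: list[tuple[QualityRead, QualityRead]]
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = self.reference.write(outdir)
        paths["r1"] = outdir / "run_R1.fastq"
        paths["r2"] = outdir / "run_R2.fastq"
        write_paired_fastq(self.pairs, paths["r1"], paths["r2"])
        paths["samplesheet"] = outdir / "samplesheet.tsv"
        self.samplesheet.to_tsv(paths["samplesheet"])
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_tsv(paths["truth"])
        return paths


def _assign_indices(
    k: int, reference: SimulatedReference
) -> tuple[str, str]:
    """Sample k gets index pair (k mod 96, (k + k//96) mod 16).

    For runs of up to 96 samples every sample carries a distinct index1,
    so a single-index hop onto a different index2 lands in an unused
    combination and is rejected at demux; larger runs remain collision-free
    in assignment (unique pairs up to the 1536-combination capacity) but
    lose that per-hop guarantee.
    """
    n1, n2 = len(reference.index1), len(reference.index2)
    i1 = reference.index1[k % n1]
    i2 = reference.index2[(k + k // n1) % n2]
    return i1, i2


def simulate_run(
    cfg: SimulationConfig,
    n_samples: int,
    reference: Optional[SimulatedReference] = None,
    genotypes: Optional[Mapping[str, Mapping[str, tuple[str, str]]]] = None,
    hop_rate: float = 0.0,
    imbalance_max: Optional[float] = None,
) -> SimulatedRun:
    """Simulate a multiplexed run: cohort genotypes (random draws unless
    given), per-sample index pairs from the dual-index scheme, combined
    FASTQ-ready pairs, a sample sheet and full ground truth.

    ``imbalance_max`` draws a per-sample-locus imbalance uniformly from
    [1, imbalance_max] instead of the fixed config ratio.  ``hop_rate``
    swaps index2 of a fraction of pairs to another sample's value.
    """
    if reference is None:
        reference = simulate_reference(cfg)
    capacity = len(reference.index1) * len(reference.index2)
    if n_samples > capacity:
        raise ValueError(
            f"n_samples {n_samples} exceeds the {capacity}-combination "
            "capacity of the index scheme"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    loci = reference.target_loci
    sheet_rows = []
    truth = GroundTruth()
    pairs: list[tuple[QualityRead, QualityRead]] = []
    serial = 0
    for k in range(n_samples):
        sample_id = f"S{k + 1:03d}"
        i1, i2 = _assign_indices(k, reference)
        sheet_rows.append((sample_id, i1, i2, f"chip{k // 48 + 1}"))
        if genotypes is not None:
            geno = dict(genotypes[sample_id])
        else:
            geno = {}
            for locus in loci:
                names = [a.name for a in reference.alleles if a.locus == locus]
                pick = rng.choice(len(names), size=2)
                geno[locus] = (names[pick[0]], names[pick[1]])
        imb = None
        if imbalance_max is not None and imbalance_max > 1.0:
            imb = {
                locus: float(rng.uniform(1.0, imbalance_max)) for locus in loci
            }
        sample_pairs, truth, serial = simulate_sample_reads(
            sample_id,
            geno,
            reference,
            cfg,
            rng=rng,
            truth=truth,
            index_pair=(i1, i2),
            serial_start=serial,
            imbalance=imb,
        )
        pairs.extend(sample_pairs)

    if hop_rate > 0 and n_samples >= 2:
        i2_by_sample = {row[0]: row[2] for row in sheet_rows}
        distinct_i2 = sorted(set(i2_by_sample.values()))
        for idx, (r1, r2) in enumerate(pairs):
            if rng.random() < hop_rate:
                rt = truth.reads[r1.read_id]
                own = i2_by_sample[rt.sample]
                others = [x for x in distinct_i2 if x != own]
                if not others:
                    continue
                new_i2 = others[int(rng.integers(len(others)))]
                r1.index2 = new_i2
                r2.index2 = new_i2
                rt.hopped = True

    samplesheet = SampleSheet(
        pd.DataFrame(sheet_rows, columns=["sample_id", "index1", "index2", "chip_id"])
    )
    return SimulatedRun(
        reference=reference,
        samplesheet=samplesheet,
        pairs=pairs,
        truth=truth,
        config=cfg,
    )
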