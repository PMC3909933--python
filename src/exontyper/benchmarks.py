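"""Whole-pipeline validation experiments on simulated cohorts.

These drivers generate data with the synthetic-data module, run the full
pipeline on it, and score the outcome against the simulator's ground
truth.  They back both the acceptance test suite and the reproduction
script; all randomness flows from the single seed argument.

Problem sizes (96 samples × 3 loci at 500 pairs per amplicon for genotype
recovery; 20 replicates for chimera-rate recovery; 500 for noise-test
calibration) are chosen as the smallest cohorts at which the binomial
error bars are decisively narrower than the effects being checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import TypingConfig, run_typing, type_sample
from .primer_qc import classify_run_pairs
from .primers import PrimerRecognizer
from .reference import ReferenceModel
from .simulate import (
    SimulationConfig,
    simulate_run,
    simulate_sample_reads,
    validation_pair_reference,
)

__all__ = [
    "cohort_recovery",
    "chimera_rate_recovery",
    "noise_calibration",
    "CohortReport",
]


def _truth_hit(call, truth_pair) -> bool:
    a, b = truth_pair
    return any(
        (a in p.group1 and b in p.group2) or (a in p.group2 and b in p.group1)
        for p in call.pairings
    )


@dataclass
class CohortReport:
    n_sample_loci: int
    n_concordant: int
    n_false_homozygous: int
    n_auto: int
    n_auto_concordant: int
    status_counts: dict

    @property
    def concordance_pct(self) -> float:
        return 100.0 * self.n_concordant / self.n_sample_loci

    @property
    def auto_concordance_pct(self) -> float:
        return 100.0 * self.n_auto_concordant / self.n_auto if self.n_auto else 100.0


def cohort_recovery(
    seed: int,
    n_samples: int = 96,
    n_loci: int = 3,
    depth: int = 500,
    error_rate: float = 0.003,
    crossover_rate: float = 0.15,
    imbalance_max: float = 5.0,
) -> CohortReport:
    """Genotype-recovery experiment at routine-workload conditions.

    A cohort with 0.3%/base sequencing error, 15% crossover chimeras and
    per-sample-locus amplification imbalance up to 5:1 is simulated,
    demultiplexed and typed; every sample-locus is scored for concordance
    with the simulated genotype within the reported ambiguity, for false
    homozygosity, and for concordance of automatically accepted calls.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_loci=n_loci,
        alleles_per_locus=12,
        depth=depth,
        crossover_rate=crossover_rate,
        error_rate=error_rate,
    )
    run = simulate_run(cfg, n_samples=n_samples, imbalance_max=imbalance_max)
    model = ReferenceModel(
        run.reference.alleles, run.reference.primers, read_length=cfg.read_length
    )
    result = run_typing(
        model,
        run.pairs,
        run.samplesheet,
        TypingConfig(),
        index1_pool=run.reference.index1,
        index2_pool=run.reference.index2,
    )
    n_concordant = n_false_homo = n_auto = n_auto_conc = 0
    status_counts: dict[str, int] = {}
    for key, call in result.calls.items():
        truth = run.truth.genotypes[key]
        hit = _truth_hit(call, truth)
        n_concordant += hit
        status_counts[call.status] = status_counts.get(call.status, 0) + 1
        if call.zygosity == "homozygous" and not hit:
            n_false_homo += 1
        if call.status == "auto":
            n_auto += 1
            n_auto_conc += hit
    return CohortReport(
        n_sample_loci=len(result.calls),
        n_concordant=n_concordant,
        n_false_homozygous=n_false_homo,
        n_auto=n_auto,
        n_auto_concordant=n_auto_conc,
        status_counts=status_counts,
    )


def chimera_rate_recovery(
    seed: int,
    n_replicates: int = 20,
    rate: float = 0.25,
    depth: int = 500,
) -> dict:
    """Recover an injected crossover fraction with the truth-based read QC.

    Each replicate simulates a heterozygous validation sample (allele pair
    divergent out to the insert ends, as QC panels are chosen) with the
    given chimera fraction, classifies every read pair against the known
    truth, and measures the crossover rate among matched pairs.
    """
    cfg = SimulationConfig(
        seed=seed,
        exon_length=240,
        depth=depth,
        crossover_rate=rate,
        error_rate=1e-3,
        exons=(2,),
    )
    reference = validation_pair_reference(cfg)
    a1, a2 = (a.name for a in reference.alleles)
    model = ReferenceModel(
        reference.alleles, reference.primers, read_length=cfg.read_length
    )
    rng = np.random.default_rng(seed)
    rates = []
    n_pairs_total = 0
    for _ in range(n_replicates):
        pairs, _, _ = simulate_sample_reads(
            "S1", {"LOC1": (a1, a2)}, reference, cfg, rng=rng
        )
        pair_cats, _ = classify_run_pairs(pairs, (a1, a2), model)
        matched = [c for c in pair_cats if c not in ("not_matched", "other_hla_allele")]
        rates.append(sum(1 for c in matched if c == "crossover") / len(matched))
        n_pairs_total += len(matched)
    mean_rate = float(np.mean(rates))
    return {
        "injected_rate": rate,
        "mean_measured_rate": mean_rate,
        "per_replicate_rates": rates,
        "n_pairs_total": n_pairs_total,
        "sigma_mean": float(np.sqrt(rate * (1 - rate) / n_pairs_total)),
    }


def noise_calibration(
    seed: int,
    n_replicates: int = 500,
    depth: int = 300,
    error_rate: float = 0.01,
) -> dict:
    """Specificity of the binomial noise test on single-allele samples.

    Each replicate sequences one homozygous allele at 1%/base error; every
    EAG other than the true one that survives the 5-best-match filter is a
    spurious group that the noise test should absorb.  Reported is the
    fraction of spurious EAGs escaping the ``noise`` label (ending up as
    result or potential new allele), to be compared with alpha.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_loci=1,
        alleles_per_locus=6,
        pairwise_divergence=2,
        exon_length=120,
        flank_length=30,
        read_length=80,
        depth=depth,
        crossover_rate=0.0,
        error_rate=error_rate,
        exons=(2,),
    )
    from .simulate import simulate_reference

    reference = simulate_reference(cfg)
    model = ReferenceModel(
        reference.alleles, reference.primers, read_length=cfg.read_length
    )
    names = sorted(a.name for a in reference.alleles)
    tcfg = TypingConfig()
    recognizer = PrimerRecognizer(model.primers, model.primer_tree, tcfg.recognition)
    cache: dict = {}
    rng = np.random.default_rng(seed)
    n_spurious = n_escapes = 0
    for r in range(n_replicates):
        name = names[r % len(names)]
        pairs, _, _ = simulate_sample_reads(
            "S1", {"LOC1": (name, name)}, reference, cfg, rng=rng
        )
        details = type_sample(
            "S1", pairs, model, tcfg, recognizer=recognizer, match_cache=cache
        )
        true_eag = model.allele_eag("LOC1", 2, name).id
        for cls in details["LOC1"].outcomes[2].classifications:
            if cls.eag_id == true_eag:
                continue
            n_spurious += 1
            if cls.label in ("result", "potential_new_allele"):
                n_escapes += 1
        if len(cache) > 400_000:  # bound memory across replicates
            cache.clear()
    return {
        "n_replicates": n_replicates,
        "n_spurious": n_spurious,
        "n_escapes": n_escapes,
        "escape_rate": (n_escapes / n_spurious) if n_spurious else 0.0,
        "escapes_per_replicate": n_escapes / n_replicates,
    }
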