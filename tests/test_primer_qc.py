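"""Truth-based read classification for primer-set evaluation."""

import numpy as np
import pytest

from exontyper.primer_qc import (
    KmerIndex,
    QcConfig,
    classify_read_qsum,
    classify_run_pairs,
    detect_crossover_read,
    kmer_prescreen,
    summarize_primer_set,
)
from exontyper.reference import ReferenceModel
from exontyper.simulate import (
    SimulationConfig,
    simulate_sample_reads,
    validation_pair_reference,
)

from conftest import make_read


@pytest.fixture(scope="module")
def db():
    rng = np.random.default_rng(42)
    seqs = {}
    for i in range(4):
        seqs[f"A*01:0{i + 1}"] = "".join(rng.choice(list("ACGT"), size=200))
    return KmerIndex(seqs, k=10)


class TestKmerPrescreen:
    def test_exact_substring_zero_mismatches(self, db):
        name = "A*01:01"
        read = make_read(db.sequences[name][20:120])
        hit = kmer_prescreen(read, db)
        assert hit == (name, 20, 0)

    def test_eleven_mismatches_not_matched(self, db):
        name = "A*01:02"
        seq = list(db.sequences[name][:150])
        for i in range(0, 11):
            pos = 40 + 7 * i
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        hit = kmer_prescreen(make_read("".join(seq)), db)
        assert hit is None

    def test_ten_mismatches_still_matched(self, db):
        name = "A*01:02"
        seq = list(db.sequences[name][:150])
        for i in range(0, 10):
            pos = 40 + 7 * i
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        hit = kmer_prescreen(make_read("".join(seq)), db)
        assert hit is not None and hit[0] == name and hit[2] == 10

    def test_random_sequence_not_matched(self, db):
        rng = np.random.default_rng(1)
        read = make_read("".join(rng.choice(list("ACGT"), size=100)))
        assert kmer_prescreen(read, db) is None


def _pair(rng, n_disc, L=120, edge=False):
    """Two sequences differing at n_disc positions (optionally end-anchored)."""
    a = "".join(rng.choice(list("ACGT"), size=L))
    if edge:
        positions = [1, 2] + list(
            np.linspace(10, L - 10, max(n_disc - 4, 1)).astype(int)
        ) + [L - 3, L - 2]
    else:
        positions = sorted(rng.choice(L, size=n_disc, replace=False))
    b = list(a)
    for p in positions:
        b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
    return a, "".join(b), sorted(set(positions))


class TestClassifyReadQsum:
    def test_error_free_read_assigned_with_zero_qsum(self):
        rng = np.random.default_rng(2)
        a1, a2, _ = _pair(rng, 6)
        cat = classify_read_qsum(
            make_read(a1), a1, a2, None, ("X*01:01", "X*02:01")
        )
        assert cat.category == "allele1"
        assert cat.q_sum_allele1 == 0.0 and cat.q_sum_allele2 > 80

    def test_qsum_over_eighty_is_not_matching(self):
        rng = np.random.default_rng(3)
        a1, a2, _ = _pair(rng, 0)  # homozygous-like: a1 == a2
        read_seq = list(a1)
        for i in (10, 30, 50):  # 3 mismatches at Q27 => Q_sum 81 > 80
            read_seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read_seq[i]]
        cat = classify_read_qsum(
            make_read("".join(read_seq), q=27), a1, a1, None, ("X*01:01", "X*01:01")
        )
        assert cat.category == "not_matched"
        # at Q_sum exactly 80 the read still matches
        cat = classify_read_qsum(
            make_read("".join(read_seq), q=[27] * 10 + [26] + [27] * 109),
            a1, a1, None, ("X*01:01", "X*01:01"),
        )
        assert cat.category == "allele1"

    def test_other_hla_allele_by_qsum_difference(self):
        rng = np.random.default_rng(4)
        other = "".join(rng.choice(list("ACGT"), size=120))
        a1, a2, _ = _pair(rng, 6)
        index = KmerIndex({"H*01:01": other, "X*01:01": a1, "X*02:01": a2})
        read = make_read(other, q=30)
        hit = kmer_prescreen(read, index)
        assert hit[0] == "H*01:01"
        cat = classify_read_qsum(read, a1, a2, hit, ("X*01:01", "X*02:01"), index)
        assert cat.category == "other_hla_allele"

    def test_tie_breaks_to_allele1(self):
        rng = np.random.default_rng(5)
        a1, a2, disc = _pair(rng, 2)
        # mutate the read at both discriminating positions to a third base
        read_seq = list(a1)
        for p in disc:
            read_seq[p] = next(
                b for b in "ACGT" if b != a1[p] and b != a2[p]
            )
        cat = classify_read_qsum(
            make_read("".join(read_seq), q=20), a1, a2, None, ("X*01:01", "X*02:01")
        )
        assert cat.q_sum_allele1 == cat.q_sum_allele2
        assert cat.category == "allele1"


class TestCrossoverRead:
    def _chimera(self, rng, bp_index=3):
        a1, a2, disc = _pair(rng, 6)
        bp = disc[bp_index] + 1
        return a1, a2, a1[:bp] + a2[bp:]

    def test_template_switch_detected(self):
        rng = np.random.default_rng(6)
        a1, a2, chim = self._chimera(rng)
        is_x, pos = detect_crossover_read(make_read(chim, q=35), a1, a2)
        assert is_x and len(pos) >= 2

    def test_single_alternate_base_insufficient(self):
        rng = np.random.default_rng(7)
        a1, a2, disc = _pair(rng, 6)
        read_seq = list(a1)
        read_seq[disc[2]] = a2[disc[2]]  # one switched base only
        is_x, pos = detect_crossover_read(make_read("".join(read_seq), q=40), a1, a2)
        assert not is_x and len(pos) == 1

    def test_low_quality_alternate_bases_ignored(self):
        rng = np.random.default_rng(8)
        a1, a2, chim = self._chimera(rng)
        # Q exactly 25 fails the "> 25" requirement
        is_x, pos = detect_crossover_read(make_read(chim, q=25), a1, a2)
        assert not is_x and pos == ()

    def test_homozygous_truth_inapplicable(self):
        rng = np.random.default_rng(9)
        a1, a2, chim = self._chimera(rng)
        is_x, _ = detect_crossover_read(
            make_read(chim, q=35), a1, a2, homozygous=True
        )
        assert not is_x


class TestSummarize:
    def _cats(self, n1, n2, nx1=0, nx2=0, other=0, unmatched=0):
        from exontyper.primer_qc import ReadCategory

        cats = []
        for cat, n in [
            ("allele1", n1), ("allele2", n2),
            ("allele1_with_crossover", nx1), ("allele2_with_crossover", nx2),
            ("other_hla_allele", other), ("not_matched", unmatched),
        ]:
            cats += [ReadCategory(f"r{cat}{i}", cat, 0.0, 0.0) for i in range(n)]
        return cats

    def test_balanced_set_passes(self):
        s = summarize_primer_set(self._cats(500, 450))
        assert s.balance.minor_major_ratio == pytest.approx(0.9)
        assert s.balance.pass_qc

    def test_twenty_percent_rule_boundary(self):
        fail = summarize_primer_set(self._cats(500, 90))
        assert fail.balance.minor_major_ratio == pytest.approx(0.18)
        assert not fail.balance.pass_qc
        edge = summarize_primer_set(self._cats(500, 100))
        assert edge.balance.pass_qc

    def test_category_partition_is_conserved(self):
        cats = self._cats(10, 8, 2, 1, 3, 4)
        s = summarize_primer_set(cats)
        assert sum(s.category_counts.values()) == len(cats)
        assert s.n_matched == 21 and s.n_crossover == 3

    def test_crossover_reads_count_toward_their_allele(self):
        s = summarize_primer_set(self._cats(400, 100, nx1=50, nx2=25))
        assert s.balance.n_allele1 == 450 and s.balance.n_allele2 == 125
        assert s.crossover_rate == pytest.approx(75 / 575)


class TestSimulatedQc:
    def _run(self, seed, crossover_rate, depth=400):
        cfg = SimulationConfig(
            seed=seed, exon_length=240, depth=depth,
            crossover_rate=crossover_rate, error_rate=1e-3, exons=(2,),
        )
        ref = validation_pair_reference(cfg)
        a1, a2 = (a.name for a in ref.alleles)
        pairs, truth, _ = simulate_sample_reads(
            "S1", {"LOC1": (a1, a2)}, ref, cfg,
            rng=np.random.default_rng(seed + 1),
        )
        model = ReferenceModel(ref.alleles, ref.primers, read_length=cfg.read_length)
        pair_cats, read_cats = classify_run_pairs(pairs, (a1, a2), model)
        return pairs, truth, pair_cats, read_cats

    def test_zero_artifact_control(self):
        pairs, truth, pair_cats, _ = self._run(seed=21, crossover_rate=0.0)
        assert all(c in ("allele1", "allele2") for c in pair_cats)
        # assignment agrees with simulator truth read for read
        a1 = "LOC1*01:01"
        for (r1, _), cat in zip(pairs, pair_cats):
            expected = "allele1" if truth.reads[r1.read_id].source == a1 else "allele2"
            assert cat == expected

    def test_injected_chimera_rate_recovered(self):
        rate = 0.15
        pairs, truth, pair_cats, _ = self._run(seed=22, crossover_rate=rate)
        n_true = sum(1 for rt in truth.reads.values() if rt.source == "chimera")
        matched = [c for c in pair_cats if c != "not_matched" and c != "other_hla_allele"]
        measured = sum(1 for c in matched if c == "crossover") / len(matched)
        sigma = np.sqrt(rate * (1 - rate) / len(pairs))
        assert measured == pytest.approx(n_true / len(pairs), abs=3 * sigma)
        assert measured == pytest.approx(rate, abs=3 * sigma)

    def test_imbalance_recovered_in_balance_ratio(self):
        cfg = SimulationConfig(
            seed=23, exon_length=240, depth=600, crossover_rate=0.0,
            error_rate=1e-3, exons=(2,), imbalance_ratio=2.0,
        )
        ref = validation_pair_reference(cfg)
        a1, a2 = (a.name for a in ref.alleles)
        pairs, truth, _ = simulate_sample_reads(
            "S1", {"LOC1": (a1, a2)}, ref, cfg, rng=np.random.default_rng(77)
        )
        model = ReferenceModel(ref.alleles, ref.primers, read_length=cfg.read_length)
        _, read_cats = classify_run_pairs(pairs, (a1, a2), model)
        s = summarize_primer_set(read_cats)
        sigma = np.sqrt(0.5 * 0.5 / len(pairs))
        assert s.balance.minor_major_ratio == pytest.approx(0.5, abs=6 * sigma)
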