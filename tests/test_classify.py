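"""Consensus building, noise testing, crossover/co-amplificate detection,
and the full classification precedence."""

import numpy as np
import pytest
from scipy import stats

from exontyper.classify import (
    AlignedRead,
    ClassificationConfig,
    ConsensusReport,
    build_consensus,
    classify_eags,
    detect_coamplification,
    detect_crossover_eag,
    detect_new_allele,
    noise_test,
)
from exontyper.matching import EagScore
from exontyper.reference import EAG, AlleleSequence

from conftest import exact_binomial_upper_tail


def _eag(eag_id, seq, locus="A", exon=2):
    return EAG(eag_id, locus, exon, seq, frozenset({f"{locus}*01:01"}))


def _reads(seq, n, q=30, offset=0):
    return [
        AlignedRead(seq, np.full(len(seq), q, dtype=np.uint8), offset)
        for _ in range(n)
    ]


class TestConsensus:
    def test_identical_reads_reproduce_reference(self):
        eag = _eag("E1", "ACGTACGTAC")
        report = build_consensus(eag, _reads("ACGTACGTAC", 10))
        assert report.consensus == "ACGTACGTAC"
        assert report.uncovered == [] and report.disagreements == []

    def test_majority_wins(self):
        eag = _eag("E1", "AAAA")
        reads = _reads("ATAA", 7) + _reads("ACAA", 3)
        report = build_consensus(eag, reads)
        assert report.consensus == "ATAA"
        assert report.disagreements == [1]

    def test_tie_breaks_toward_reference(self):
        eag = _eag("E1", "AAAA")
        reads = _reads("ATAA", 5) + _reads("AAAA", 5)
        assert build_consensus(eag, reads).consensus == "AAAA"

    def test_zero_coverage_position_flagged_and_filled(self):
        eag = _eag("E1", "ACGTACGT")
        report = build_consensus(eag, _reads("ACGT", 4, offset=0))
        assert report.consensus == "ACGTACGT"
        assert report.uncovered == [4, 5, 6, 7]

    def test_noisy_reads_converge_to_truth(self):
        rng = np.random.default_rng(8)
        truth = "".join(rng.choice(list("ACGT"), size=120))
        eag = _eag("E1", truth)
        reads = []
        for _ in range(300):  # 1% uniform errors
            arr = list(truth)
            for i in range(len(arr)):
                if rng.random() < 0.01:
                    arr[i] = "ACGT"[rng.integers(4)]
            reads.append(AlignedRead("".join(arr), np.full(120, 20, np.uint8), 0))
        assert build_consensus(eag, reads).consensus == truth


class TestNewAllele:
    def test_systematic_snp_reported(self):
        rng = np.random.default_rng(4)
        ref_seq = "".join(rng.choice(list("ACGT"), size=100))
        novel = ref_seq[:50] + ("A" if ref_seq[50] != "A" else "C") + ref_seq[51:]
        eag = _eag("E1", ref_seq)
        report = build_consensus(eag, _reads(novel, 200, q=35))
        snps = detect_new_allele(report, eag)
        assert snps == [(50, ref_seq[50], novel[50])]

    def test_random_noise_is_not_a_snp(self):
        rng = np.random.default_rng(5)
        ref_seq = "".join(rng.choice(list("ACGT"), size=100))
        eag = _eag("E1", ref_seq)
        reads = []
        for _ in range(200):
            arr = list(ref_seq)
            for i in range(len(arr)):
                if rng.random() < 0.01:
                    arr[i] = "ACGT"[rng.integers(4)]
            reads.append(AlignedRead("".join(arr), np.full(100, 30, np.uint8), 0))
        assert detect_new_allele(build_consensus(eag, reads), eag) is None

    def test_zero_reads_none(self):
        eag = _eag("E1", "ACGT")
        assert detect_new_allele(build_consensus(eag, []), eag) is None


class TestNoiseTest:
    def test_single_position_closed_form(self):
        """1 low read among 991 with one Q30 discriminating position:
        expected conversions ≈ 1, so the singleton is plainly noise."""
        high = _eag("H", "A" * 50)
        low = _eag("L", "A" * 25 + "C" + "A" * 24)
        res = noise_test(
            EagScore("L", 1, 1, 1),
            EagScore("H", 990, 990, 990),
            low,
            high,
            _reads("A" * 50, 30, q=30),
        )
        assert res.p_error_est == pytest.approx(1e-3, rel=1e-9)
        expected = exact_binomial_upper_tail(1, 991, 1e-3)
        assert res.p_value == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.6290, abs=5e-4)
        assert res.is_noise

    def test_three_positions_cannot_explain_twenty_reads(self):
        high_seq = "A" * 60
        low_seq = "C" + "A" * 29 + "C" + "A" * 28 + "C"
        res = noise_test(
            EagScore("L", 20, 20, 20),
            EagScore("H", 980, 980, 980),
            _eag("L", low_seq),
            _eag("H", high_seq),
            _reads(high_seq, 50, q=30),
        )
        assert res.p_error_est == pytest.approx(1e-9, rel=1e-9)
        assert res.p_value < 1e-30
        assert not res.is_noise

    def test_zero_low_reads_trivially_noise(self):
        res = noise_test(
            EagScore("L", 0, 0, 0),
            EagScore("H", 100, 100, 100),
            _eag("L", "AC"),
            _eag("H", "AA"),
            _reads("AA", 10),
        )
        assert res.p_value == 1.0 and res.is_noise

    def test_identical_eags_inapplicable(self):
        with pytest.raises(ValueError, match="identical"):
            noise_test(
                EagScore("L", 1, 1, 1),
                EagScore("H", 9, 9, 9),
                _eag("L", "AAAA"),
                _eag("H", "AAAA"),
                _reads("AAAA", 5),
            )

    def test_p_values_match_exact_binomial_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n = int(rng.integers(10, 2000))
            k = int(rng.integers(0, min(n, 50)))
            p = float(10 ** rng.uniform(-6, -0.3))
            ours = float(stats.binom.sf(k - 1, n, p)) if k > 0 else 1.0
            oracle = exact_binomial_upper_tail(k, n, p)
            assert ours == pytest.approx(oracle, abs=1e-9, rel=1e-6)


def _report(eag_id, consensus):
    n = len(consensus)
    return ConsensusReport(
        eag_id, consensus, np.zeros((n, 4), int), np.zeros((n, 4)),
        np.ones(n, int), [], [], 1,
    )


class TestCrossoverEag:
    def test_constructed_chimera_found(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "TGCATGCATGCATGCATGCA"
        cand = a[:12] + b[12:]
        hit = detect_crossover_eag(
            _report("C", cand), [_report("A", a), _report("B", b)]
        )
        assert hit is not None
        bp, i, j = hit
        assert (i, j) == ("A", "B")
        assert cand == a[:bp] + b[bp:]

    def test_non_chimera_not_flagged(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "TGCATGCATGCATGCATGCA"
        cand = a[:12] + b[12:-1] + "G"  # extra mismatch vs every combination
        assert cand[-1] != a[-1] and cand[-1] != b[-1]
        assert detect_crossover_eag(
            _report("C", cand), [_report("A", a), _report("B", b)]
        ) is None

    def test_requires_two_higher_reports(self):
        a = "ACGTACGT"
        assert detect_crossover_eag(_report("C", a), [_report("A", a)]) is None


class TestCoamplification:
    def _alleles(self):
        return {
            "A*01:01": AlleleSequence("A*01:01", "A", {2: "ACGTACGTAC"}),
            "A*01:02": AlleleSequence("A*01:02", "A", {2: "ACGTACGTTT"}),
            "H*01:01": AlleleSequence("H*01:01", "H", {2: "ACGAACGTAC"}),
        }

    def test_paralog_consensus_detected(self):
        hit = detect_coamplification(
            _report("E", "ACGAACGTAC"), self._alleles(), target_locus="A", exon=2
        )
        assert hit is not None and hit[0] == "H"

    def test_on_target_consensus_not_flagged(self):
        assert detect_coamplification(
            _report("E", "ACGTACGTAC"), self._alleles(), target_locus="A", exon=2
        ) is None


class TestClassifyPrecedence:
    def _scored(self, layout):
        return [EagScore(e, n, n, n) for e, n in layout]

    def _setup(self, seqs):
        eag_by_id = {e: _eag(e, s) for e, s in seqs.items()}
        alleles = {
            f"A*01:0{i}": AlleleSequence(f"A*01:0{i}", "A", {2: s})
            for i, s in enumerate(seqs.values(), 1)
        }
        return eag_by_id, alleles

    def test_one_in_fifty_discard_boundary(self):
        seq_top = "A" * 40
        seqs = {"T": seq_top, "X": "C" * 40, "Y": "G" * 40}
        eag_by_id, alleles = self._setup(seqs)
        reads = {e: _reads(s, 5) for e, s in seqs.items()}
        out = classify_eags(
            self._scored([("T", 1000), ("X", 20), ("Y", 19)]),
            reads, eag_by_id, alleles, "A", 2,
        )
        labels = {c.eag_id: c.label for c in out.classifications}
        assert labels["Y"] == "discarded"  # 19 < 1000/50
        assert labels["X"] != "discarded"  # exactly 20 is retained

    def test_chimera_of_results_is_crossover_not_coamp(self):
        a = "ACGT" * 10
        b = "TGCA" * 10
        chim = a[:20] + b[20:]
        seqs = {"A": a, "B": b, "C": chim}
        eag_by_id, alleles = self._setup(seqs)
        # the paralog H is far from the chimera: precedence must pick crossover
        alleles["H*01:01"] = AlleleSequence("H*01:01", "H", {2: "G" * 40})
        reads = {e: _reads(s, 50) for e, s in seqs.items()}
        out = classify_eags(
            self._scored([("A", 500), ("B", 480), ("C", 90)]),
            reads, eag_by_id, alleles, "A", 2,
        )
        labels = {c.eag_id: c.label for c in out.classifications}
        assert labels == {"A": "result", "B": "result", "C": "crossover"}

    def test_more_than_two_results_warns_or_errors(self):
        seqs = {"A": "A" * 40, "B": "C" * 40, "C": "G" * 40}
        eag_by_id, alleles = self._setup(seqs)
        reads = {e: _reads(s, 20, q=35) for e, s in seqs.items()}
        # small third result: warning
        out = classify_eags(
            self._scored([("A", 500), ("B", 480), ("C", 60)]),
            reads, eag_by_id, alleles, "A", 2,
        )
        assert len(out.result_eags()) == 3
        assert out.warnings and not out.errors
        # comparable third result: error
        out = classify_eags(
            self._scored([("A", 500), ("B", 480), ("C", 200)]),
            reads, eag_by_id, alleles, "A", 2,
        )
        assert out.errors

    def test_noise_versus_genuine_minor_eag(self):
        top = "A" * 50
        low = "A" * 20 + "C" + "A" * 29  # one discriminating position
        seqs = {"T": top, "L": low}
        eag_by_id, alleles = self._setup(seqs)
        # Q20 reads: per-read conversion probability 1e-2, so among ~100
        # reads an expected ~1 conversion easily explains 2 observed...
        out = classify_eags(
            self._scored([("T", 100), ("L", 2)]),
            {"T": _reads(top, 100, q=20), "L": _reads(low, 2, q=20)},
            eag_by_id, alleles, "A", 2,
        )
        assert {c.eag_id: c.label for c in out.classifications}["L"] == "noise"
        # ... while 20 of 420 reads cannot be error conversions
        out2 = classify_eags(
            self._scored([("T", 400), ("L", 20)]),
            {"T": _reads(top, 400, q=20), "L": _reads(low, 20, q=20)},
            eag_by_id, alleles, "A", 2,
        )
        labels = {c.eag_id: c.label for c in out2.classifications}
        assert labels == {"T": "result", "L": "result"}
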