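"""PEAG matching, per-read EAG assignment and evidence scoring."""

import numpy as np
import pytest

from exontyper.matching import (
    EagScore,
    ReadEagAssignment,
    assign_read,
    match_read_to_peags,
    score_eags,
)
from exontyper.primers import RecognitionConfig, qp_arrays
from exontyper.reference import (
    AlleleSequence,
    ReferenceModel,
    build_eags,
    build_peags,
    reverse_complement,
)
from exontyper.simulate import SimulationConfig, simulate_reference, simulate_sample_reads
from exontyper.trie import MatchTree

from conftest import brute_force_match_probs, make_read


def _peag_tree(peags, flank_start=None):
    return MatchTree.from_sequences(
        [(p.partial_sequence, p.id) for p in peags], flank_start=flank_start
    )


class TestMatchReadToPeags:
    def test_error_free_read_ranks_its_peag_first(self, sim_model):
        cfg, ref, model = sim_model
        allele = ref.alleles[0]
        insert = allele.exon_seqs[2][: model.read_span]
        read = make_read(insert, q=35)
        tree = model.peag_trees[(allele.locus, 2, "forward")]
        hits = match_read_to_peags(read, tree)
        assert hits
        top_peag, top_p = hits[0]
        assert allele.locus in top_peag
        true_eag = model.allele_eag(allele.locus, 2, allele.name)
        assert true_eag.id in model.peag_members[top_peag]
        assert all(p < top_p for _, p in hits[1:])

    def test_short_read_scored_over_covered_prefix(self, sim_model):
        cfg, ref, model = sim_model
        allele = ref.alleles[0]
        tree = model.peag_trees[(allele.locus, 2, "forward")]
        read = make_read(allele.exon_seqs[2][:50], q=30)
        hits = dict(match_read_to_peags(read, tree))
        expected = 0.999 ** 50
        peag = next(
            p for p in model.peags[(allele.locus, 2, "forward")]
            if model.allele_eag(allele.locus, 2, allele.name).id in p.member_eags
        )
        assert hits[peag.id] == pytest.approx(expected, rel=1e-9)

    def test_tree_equals_exhaustive_oracle(self, sim_model):
        cfg, ref, model = sim_model
        recog = RecognitionConfig()
        rng = np.random.default_rng(23)
        bases = "ACGT"
        for locus in model.loci:
            peags = model.peags[(locus, 2, "forward")]
            assert len(peags) <= 30
            tree = model.peag_trees[(locus, 2, "forward")]
            for _ in range(25):
                src = peags[rng.integers(len(peags))].partial_sequence
                seq = list(src)
                for _ in range(rng.integers(0, 3)):
                    seq[rng.integers(len(seq))] = bases[rng.integers(4)]
                seq = "".join(seq)
                quals = rng.integers(15, 41, size=len(seq))
                got = dict(
                    match_read_to_peags(make_read(seq, q=quals), tree, recog)
                )
                expected = brute_force_match_probs(
                    seq,
                    quals,
                    [(p.id, p.partial_sequence) for p in peags],
                    recog.p_min,
                )
                assert set(got) == set(expected)
                for pid, p in expected.items():
                    assert got[pid] == pytest.approx(p, rel=1e-12)

    def test_intronic_indel_tolerated_within_flank(self):
        # short exon so the covered span reaches into the 3' intron
        a = AlleleSequence(
            "A*01:01",
            "A",
            {2: "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"},  # 40 bases
            {(2, "5p"): "G" * 20, (2, "3p"): "TTGGCCAATTGGCCAATTGG"},
        )
        eags = build_eags([a], "A", 2)
        peags = build_peags(eags, read_span=52, direction="forward", alleles={"A*01:01": a})
        tree = _peag_tree(peags, flank_start=40)
        partial = peags[0].partial_sequence
        assert len(partial) == 52
        # delete one base inside the intronic segment (position 45)
        mutated = partial[:45] + partial[46:]
        read = make_read(mutated, q=30)
        hits = dict(match_read_to_peags(read, tree))
        assert peags[0].id in hits
        # gap-free matching of the same read fails badly
        qp, omqp = qp_arrays(read.quals)
        gap_free = tree.walk_probabilities(
            mutated.encode(), qp, omqp, 1e-4, allow_indels=False
        )
        assert hits[peags[0].id] > gap_free.get(peags[0].id, 0.0)


class TestAssignRead:
    def test_multi_eag_peag_is_a_tie(self):
        index = {"P1": frozenset({"E1", "E2", "E3"})}
        a = assign_read([("P1", 0.97)], index, "r")
        assert a.best == {"E1", "E2", "E3"}
        assert not a.single_best
        assert len(a.candidates) == 3

    def test_clear_winner_is_single_best(self):
        index = {"P1": frozenset({"E1"}), "P2": frozenset({"E2"})}
        a = assign_read([("P1", 0.99), ("P2", 0.40)], index, "r")
        assert a.best == {"E1"} and a.single_best

    def test_empty_candidates_mean_unexplained_read(self):
        a = assign_read([], {}, "r")
        assert not a.assigned and a.best == frozenset()

    def test_eag_probability_is_max_over_peags(self):
        index = {"P1": frozenset({"E1"}), "P2": frozenset({"E1", "E2"})}
        a = assign_read([("P1", 0.5), ("P2", 0.9)], index, "r")
        assert dict(a.candidates)["E1"] == 0.9


class TestScoreEags:
    def _assignments(self, layout):
        """layout: list of (candidates, best, single)"""
        out = []
        for i, (cands, best, single) in enumerate(layout):
            out.append(
                ReadEagAssignment(f"r{i}", [(c, 0.9) for c in cands], frozenset(best), single)
            )
        return out

    def test_five_best_match_minimum_boundary(self):
        four = self._assignments([(["E1"], ["E1"], True)] * 4)
        five = self._assignments([(["E1"], ["E1"], True)] * 5)
        assert score_eags(four) == []
        scores = score_eags(five)
        assert len(scores) == 1 and scores[0].n_best == 5

    def test_counts_equal_brute_tally(self):
        rng = np.random.default_rng(3)
        eags = ["E1", "E2", "E3"]
        layout = []
        for _ in range(300):
            cands = [e for e in eags if rng.random() < 0.7] or ["E1"]
            best = [cands[rng.integers(len(cands))]]
            if len(cands) > 1 and rng.random() < 0.3:
                best = cands[:2]
            layout.append((cands, best, len(best) == 1))
        assignments = self._assignments(layout)
        scores = {s.eag_id: s for s in score_eags(assignments, min_best=1)}
        for eag in eags:
            n_match = sum(1 for c, _, _ in layout if eag in c)
            n_best = sum(1 for _, b, _ in layout if eag in b)
            n_single = sum(1 for _, b, s in layout if eag in b and s)
            if n_best >= 1:
                s = scores[eag]
                assert (s.n_match, s.n_best, s.n_single_best) == (n_match, n_best, n_single)
                assert s.n_single_best <= s.n_best <= s.n_match

    def test_ranked_by_best_matches_descending(self):
        layout = [(["E1"], ["E1"], True)] * 9 + [(["E2"], ["E2"], True)] * 6
        scores = score_eags(self._assignments(layout))
        assert [s.eag_id for s in scores] == ["E1", "E2"]


class TestSimulatedEvidence:
    def test_heterozygote_reads_are_single_best_for_their_allele(self, sim_model):
        cfg, ref, model = sim_model
        locus = "LOC1"
        names = [a.name for a in ref.alleles if a.locus == locus][:2]
        sim_cfg = SimulationConfig(
            seed=31, n_loci=2, alleles_per_locus=6, pairwise_divergence=6,
            depth=250, crossover_rate=0.0, error_rate=0.0, exons=(2,),
        )
        pairs, truth, _ = simulate_sample_reads(
            "S1", {locus: (names[0], names[1])}, ref, sim_cfg,
            rng=np.random.default_rng(1),
        )
        e1 = model.allele_eag(locus, 2, names[0]).id
        e2 = model.allele_eag(locus, 2, names[1]).id
        assert e1 != e2
        tree = model.peag_trees[(locus, 2, "forward")]
        n_checked = 0
        for r1, _ in pairs:
            src = truth.reads[r1.read_id].source
            insert = make_read(r1.sequence[sim_cfg.primer_length:], q=r1.quals[sim_cfg.primer_length:])
            a = assign_read(
                match_read_to_peags(insert, tree), model.peag_members, r1.read_id
            )
            expected = e1 if src == names[0] else e2
            if a.single_best:
                assert a.best == {expected}
                n_checked += 1
        # the two alleles differ within the forward span here
        assert n_checked == len(pairs)

    def test_both_directions_rank_true_eags_top(self, sim_model):
        """Forward-only and reverse-only evidence must agree on the winners."""
        cfg, ref, model = sim_model
        locus = "LOC2"
        names = [a.name for a in ref.alleles if a.locus == locus][:2]
        sim_cfg = SimulationConfig(
            seed=37, n_loci=2, alleles_per_locus=6, pairwise_divergence=6,
            depth=150, crossover_rate=0.0, error_rate=0.0, exons=(2,),
        )
        pairs, truth, _ = simulate_sample_reads(
            "S1", {locus: (names[0], names[1])}, ref, sim_cfg,
            rng=np.random.default_rng(2),
        )
        expected = {
            model.allele_eag(locus, 2, n).id for n in names
        }
        for direction, mate in (("forward", 0), ("reverse", 1)):
            tree = model.peag_trees[(locus, 2, direction)]
            assignments = []
            for pair in pairs:
                read = pair[mate]
                insert = make_read(
                    read.sequence[sim_cfg.primer_length:],
                    q=read.quals[sim_cfg.primer_length:],
                )
                assignments.append(
                    assign_read(match_read_to_peags(insert, tree), model.peag_members)
                )
            scores = score_eags(assignments)
            assert {s.eag_id for s in scores[:2]} == expected
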