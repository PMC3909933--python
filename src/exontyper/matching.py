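"""Per-read PEAG matching and per-EAG evidence accumulation.

A primer-clipped read is matched against all PEAGs of its locus, exon and
direction with the same quality-weighted tree walk used for primer
recognition.  Matched PEAGs contribute their member EAGs at the PEAG's
probability (a read's support for an EAG is the best explanation, i.e. the
max over its matching PEAGs).  Per EAG, three counters accumulate:

* ``n_match``        — reads similar enough to the EAG at all (p ≥ p_min);
* ``n_best``         — reads whose maximal-probability EAG set contains it;
* ``n_single_best``  — reads for which it is the unique arg-max.

Only EAGs with at least ``min_best`` (default 5) best-match reads are
carried forward, ranked by ``n_best`` descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .primers import RecognitionConfig, qp_arrays
from .readio import QualityRead
from .trie import MatchTree

__all__ = [
    "ReadEagAssignment",
    "EagScore",
    "match_read_to_peags",
    "assign_read",
    "score_eags",
    "MIN_BEST_MATCH_READS",
]

# an EAG is considered only with at least this many best-match reads
MIN_BEST_MATCH_READS = 5

# relative tolerance for arg-max ties between float products
_TIE_RTOL = 1e-9


@dataclass(slots=True)
class ReadEagAssignment:
    read_id: str
    candidates: list[tuple[str, float]]  # (eag_id, p_eag)
    best: frozenset[str]
    single_best: bool
    direction: str = "forward"

    @property
    def assigned(self) -> bool:
        return bool(self.candidates)


@dataclass(slots=True)
class EagScore:
    eag_id: str
    n_match: int = 0
    n_best: int = 0
    n_single_best: int = 0


def match_read_to_peags(
    insert: QualityRead,
    peag_tree: MatchTree,
    cfg: Optional[RecognitionConfig] = None,
) -> list[tuple[str, float]]:
    """Probability of each PEAG explaining a primer-clipped read.

    Reads shorter than a partial sequence are scored over the covered
    prefix; reads extending past the stored span have their extra bases
    ignored.  Returns (peag_id, p) sorted by descending probability, empty
    when nothing survives the ``p_min`` floor.
    """
    cfg = cfg or RecognitionConfig()
    qp, omqp = qp_arrays(insert.quals)
    probs = peag_tree.walk_probabilities(
        insert.sequence.encode("ascii"),
        qp,
        omqp,
        cfg.p_min,
        indel_penalty=cfg.indel_penalty,
        max_indels=cfg.max_indels,
    )
    return sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))


def assign_read(
    candidates: Sequence[tuple[str, float]],
    peag_index: Mapping[str, frozenset[str]],
    read_id: str = "",
    direction: str = "forward",
) -> ReadEagAssignment:
    """Lift PEAG probabilities onto EAGs and take the arg-max set.

    Each candidate PEAG contributes its member EAGs at its probability; an
    EAG matched through several PEAGs keeps the maximum.  All EAGs tied at
    the maximum (within floating-point tolerance) are "best"; the read is
    "single best" only when that set is a singleton.
    """
    p_eag: dict[str, float] = {}
    for peag_id, p in candidates:
        for eag_id in peag_index[peag_id]:
            if p > p_eag.get(eag_id, 0.0):
                p_eag[eag_id] = p
    if not p_eag:
        return ReadEagAssignment(read_id, [], frozenset(), False, direction)
    p_max = max(p_eag.values())
    cutoff = p_max * (1.0 - _TIE_RTOL)
    best = frozenset(e for e, p in p_eag.items() if p >= cutoff)
    ranked = sorted(p_eag.items(), key=lambda kv: (-kv[1], kv[0]))
    return ReadEagAssignment(read_id, ranked, best, len(best) == 1, direction)


def score_eags(
    assignments: Iterable[ReadEagAssignment],
    min_best: int = MIN_BEST_MATCH_READS,
) -> list[EagScore]:
    """Tally per-EAG evidence over both read directions and filter/rank.

    EAGs scoring fewer than ``min_best`` best-match reads are dropped; the
    rest are ranked by ``n_best`` descending (ties broken by id for
    determinism).
    """
    scores: dict[str, EagScore] = {}
    for a in assignments:
        for eag_id, _ in a.candidates:
            scores.setdefault(eag_id, EagScore(eag_id)).n_match += 1
        for eag_id in a.best:
            s = scores[eag_id]
            s.n_best += 1
            if a.single_best:
                s.n_single_best += 1
    kept = [s for s in scores.values() if s.n_best >= min_best]
    kept.sort(key=lambda s: (-s.n_best, s.eag_id))
    return kept
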