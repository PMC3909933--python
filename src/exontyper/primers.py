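"""Three-level primer recognition.

Every read of a well-formed amplicon begins with its target-specific
primer, which identifies the locus, exon and direction of the read.
Recognition proceeds in three levels of increasing cost:

1. exact string comparison of the read prefix against the primer library
   (IUPAC degeneracy in the primer counts as agreement);
2. exact lookup of the leading bases in a table of previously resolved
   artifact prefixes;
3. a probabilistic walk of the primer tree: starting from p = 1, each
   agreeing base multiplies by Q_p and each disagreeing base by (1 − Q_p),
   branches are pruned below ``p_min``, and the best primer is retained
   only when its probability exceeds the runner-up by the dominance ratio.
   Successful level-3 resolutions are memoized in the artifact table so
   the same leading sequence is answered at level 2 next time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .readio import QualityRead
from .trie import MatchTree, iupac_compatible

__all__ = [
    "q_to_prob",
    "RecognitionConfig",
    "PrimerMatch",
    "ArtifactTable",
    "PrimerRecognizer",
    "clip_primer",
]

# correct-call probability per Phred score, Q_p = 1 - 10^(-Q/10)
_QP_TABLE = tuple(1.0 - 10.0 ** (-q / 10.0) for q in range(94))
_OMQP_TABLE = tuple(10.0 ** (-q / 10.0) for q in range(94))


def q_to_prob(q) -> float:
    """Correct-call probability Q_p = 1 − 10^(−Q/10) for a Phred score."""
    arr = np.asarray(q)
    if np.any(arr < 0):
        raise ValueError("Phred scores must be non-negative")
    out = 1.0 - 10.0 ** (-arr / 10.0)
    return float(out) if out.ndim == 0 else out


def qp_arrays(quals: np.ndarray) -> tuple[list[float], list[float]]:
    """Per-position (Q_p, 1−Q_p) as plain lists for the trie walk."""
    qp = np.take(_QP_TABLE, quals)
    omqp = np.take(_OMQP_TABLE, quals)
    return qp.tolist(), omqp.tolist()


@dataclass(slots=True)
class RecognitionConfig:
    """Floor and dominance criterion for probabilistic matching.

    ``p_min``: branches with running probability below this are abandoned;
    the default 1e-4 admits roughly one high-quality mismatch on an
    otherwise high-quality primer.  ``dominance_ratio``: the best
    probability must be at least this multiple of the runner-up (ties at
    exactly the ratio are retained).
    """

    p_min: float = 1e-4
    dominance_ratio: float = 10.0
    indel_penalty: float = 1e-3
    max_indels: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.p_min < 1.0:
            raise ValueError("p_min must be in (0, 1)")
        if self.dominance_ratio <= 1.0:
            raise ValueError("dominance_ratio must exceed 1")


@dataclass(slots=True)
class PrimerMatch:
    read_id: str
    primer_id: Optional[str]
    level: int  # 1 | 2 | 3; 0 when unmatched
    p_primer: float = 0.0
    runner_up_p: float = 0.0
    primer_length: int = 0

    @property
    def matched(self) -> bool:
        return self.primer_id is not None


@dataclass
class ArtifactTable:
    """Exact-lookup memo of leading sequences resolved at level 3.

    Keys are fixed-length read prefixes (longest primer length); values the
    resolved primer id.  Persistable to TSV (``leading_sequence  primer_id``)
    so a table can be carried across runs.
    """

    key_length: int
    table: dict[str, tuple[str, float, int]] = field(default_factory=dict)

    def lookup(self, leading: str) -> Optional[tuple[str, float, int]]:
        return self.table.get(leading)

    def add(self, leading: str, primer_id: str, p: float, primer_length: int) -> None:
        self.table[leading] = (primer_id, p, primer_length)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("leading_sequence\tprimer_id\n")
            for key, (pid, _, _) in sorted(self.table.items()):
                fh.write(f"{key}\t{pid}\n")

    @classmethod
    def from_tsv(cls, path, primer_lengths: dict[str, int]) -> "ArtifactTable":
        table: dict[str, tuple[str, float, int]] = {}
        key_length = 0
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("leading_sequence")
            for line in fh:
                key, pid = line.rstrip("\n").split("\t")
                table[key] = (pid, 1.0, primer_lengths[pid])
                key_length = len(key)
        return cls(key_length=key_length, table=table)


class PrimerRecognizer:
    """Stateful three-level primer recognition over one primer library."""

    def __init__(
        self,
        primers: Sequence,
        tree: MatchTree,
        cfg: Optional[RecognitionConfig] = None,
        artifacts: Optional[ArtifactTable] = None,
    ) -> None:
        self.primers = list(primers)
        self.tree = tree
        self.cfg = cfg or RecognitionConfig()
        max_len = max(len(p.sequence) for p in self.primers)
        self.artifacts = artifacts or ArtifactTable(key_length=max_len)
        self.primer_by_id = {p.id: p for p in self.primers}
        # level 1: exact dict for non-degenerate primers, scan list otherwise
        self._exact: dict[str, object] = {}
        self._degenerate: list = []
        for p in self.primers:
            if set(p.sequence) <= set("ACGT"):
                self._exact[p.sequence] = p
            else:
                self._degenerate.append(p)
        self._lengths = sorted({len(p.sequence) for p in self.primers}, reverse=True)

    def recognize(self, read: QualityRead) -> PrimerMatch:
        seq = read.sequence
        # level 1: exact prefix match (longest primer first)
        for length in self._lengths:
            prefix = seq[:length]
            hit = self._exact.get(prefix)
            if hit is not None and len(hit.sequence) == length:
                return PrimerMatch(read.read_id, hit.id, 1, 1.0, 0.0, length)
        for p in self._degenerate:
            ps = p.sequence
            if len(seq) >= len(ps) and all(
                iupac_compatible(a, b) for a, b in zip(ps, seq)
            ):
                return PrimerMatch(read.read_id, p.id, 1, 1.0, 0.0, len(ps))
        # level 2: artifact look-up of the leading bases
        leading = seq[: self.artifacts.key_length]
        known = self.artifacts.lookup(leading)
        if known is not None:
            pid, p, plen = known
            return PrimerMatch(read.read_id, pid, 2, p, 0.0, plen)
        # level 3: probabilistic tree walk
        qp, omqp = qp_arrays(read.quals)
        probs = self.tree.walk_probabilities(
            seq.encode("ascii"),
            qp,
            omqp,
            self.cfg.p_min,
            allow_indels=False,
        )
        if not probs:
            return PrimerMatch(read.read_id, None, 0)
        ranked = sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))
        best_id, best_p = ranked[0]
        second_p = ranked[1][1] if len(ranked) > 1 else 0.0
        if best_p < self.cfg.dominance_ratio * second_p:
            return PrimerMatch(read.read_id, None, 0, best_p, second_p)
        plen = len(self.primer_by_id[best_id].sequence)
        self.artifacts.add(leading, best_id, best_p, plen)
        return PrimerMatch(read.read_id, best_id, 3, best_p, second_p, plen)


def clip_primer(read: QualityRead, match: PrimerMatch) -> QualityRead:
    """Remove the matched primer span (bases and qualities) from the 5' end.

    Returns a new read; the caller keeps the original for audit.
    """
    if not match.matched:
        raise ValueError(f"read {read.read_id}: cannot clip an unmatched primer")
    k = match.primer_length
    return QualityRead(
        read_id=read.read_id,
        mate=read.mate,
        sequence=read.sequence[k:],
        quals=read.quals[k:],
        index1=read.index1,
        index2=read.index2,
    )
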