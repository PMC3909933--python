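"""Quality-score-weighted trie matching.

Primer sequences and PEAG partial sequences are stored in a prefix tree.
A read is matched by walking every branch while maintaining a running
probability: starting at 1, each agreeing base multiplies by
Q_p = 1 − 10^(−Q/10) (the correct-call probability) and each disagreeing
base by (1 − Q_p).  All factors are ≤ 1, so the running probability is
non-increasing and a branch can be abandoned the moment it drops below a
floor ``p_min`` — the depth-first walk with pruning is exactly equivalent
to the brute-force per-candidate product wherever that product is ≥ p_min.

Single-base insertion/deletion branches are admitted only within intronic
flank segments of PEAG partial sequences (positions ≥ ``flank_start``),
bounded to a few events per path; exon bodies are matched gap-free.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

__all__ = ["MatchTree", "build_primer_tree", "IUPAC", "iupac_compatible"]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def iupac_compatible(a: str, b: str) -> bool:
    """True when the base sets of two (possibly degenerate) codes intersect."""
    return bool(set(IUPAC.get(a, a)) & set(IUPAC.get(b, b)))


# node layout: [children: dict[int,node], leaves: list[str]|None,
#              single: (int, node)|None, subtree_leaves: list[str]]
def _new_node() -> list:
    return [{}, None, None, None]


class MatchTree:
    """Prefix tree over sequences with per-leaf payload ids."""

    def __init__(self, flank_start: Optional[int] = None) -> None:
        self.root = _new_node()
        self.flank_start = flank_start
        self.entries: list[tuple[str, str]] = []  # (sequence, payload)

    # -- construction -------------------------------------------------------

    def insert(self, sequence: str, payload: str, expand_iupac: bool = False) -> None:
        self.entries.append((sequence, payload))
        paths: list[list] = [self.root]
        for ch in sequence.upper():
            expansions = IUPAC.get(ch, ch) if expand_iupac else ch
            next_paths: list[list] = []
            for base in expansions:
                b = ord(base)
                for node in paths:
                    child = node[0].get(b)
                    if child is None:
                        child = _new_node()
                        node[0][b] = child
                    next_paths.append(child)
            paths = next_paths
        for node in paths:
            if node[1] is None:
                node[1] = []
            if payload not in node[1]:
                node[1].append(payload)

    @classmethod
    def from_sequences(
        cls,
        pairs: Iterable[tuple[str, str]],
        flank_start: Optional[int] = None,
        expand_iupac: bool = False,
    ) -> "MatchTree":
        tree = cls(flank_start=flank_start)
        for seq, payload in pairs:
            tree.insert(seq, payload, expand_iupac=expand_iupac)
        tree.finalize()
        return tree

    def finalize(self) -> None:
        """Precompute unary-chain shortcuts and subtree leaf lists."""

        def visit(node: list) -> list[str]:
            children, leaves, _, _ = node
            below: list[str] = list(leaves) if leaves else []
            for child in children.values():
                below.extend(visit(child))
            node[3] = below
            node[2] = next(iter(children.items())) if len(children) == 1 else None
            return below

        visit(self.root)

    # -- queries ------------------------------------------------------------

    def walk_exact(self, sequence: str) -> list[str]:
        """Payloads whose stored path is base-compatible with ``sequence``.

        IUPAC codes in the query are treated as compatibility classes, so a
        degenerate primer's literal sequence reaches its own leaf.
        """
        hits: list[str] = []
        nodes = [self.root]
        for ch in sequence.upper():
            nxt: list[list] = []
            for node in nodes:
                for b, child in node[0].items():
                    if iupac_compatible(chr(b), ch):
                        nxt.append(child)
            if not nxt:
                return []
            nodes = nxt
        for node in nodes:
            if node[1]:
                hits.extend(node[1])
        return sorted(set(hits))

    def walk_probabilities(
        self,
        seq: bytes,
        qp: Sequence[float],
        omqp: Sequence[float],
        p_min: float,
        indel_penalty: float = 1e-3,
        max_indels: int = 3,
        allow_indels: bool = True,
    ) -> dict[str, float]:
        """Probability of every stored sequence explaining the read.

        ``seq`` is the read as bytes; ``qp``/``omqp`` are the per-position
        correct-call and error probabilities.  A payload's value is the
        maximum path probability over all its paths (degenerate expansions,
        indel variants).  Reads shorter than a stored sequence are scored
        over the covered prefix; read bases beyond a stored sequence's end
        are ignored.
        """
        results: dict[str, float] = {}
        n = len(seq)
        flank_start = self.flank_start if allow_indels else None
        stack: list[tuple[list, int, float, int]] = [(self.root, 0, 1.0, max_indels)]
        get = results.get
        while stack:
            node, pos, p, budget = stack.pop()
            while True:
                children, leaves, single, below = node
                if leaves:
                    for pid in leaves:
                        if p > get(pid, 0.0):
                            results[pid] = p
                if pos >= n:
                    if children:
                        for pid in below:
                            if p > get(pid, 0.0):
                                results[pid] = p
                    break
                if not children:
                    break
                in_flank = (
                    flank_start is not None and budget > 0 and pos >= flank_start
                )
                if single is not None and not in_flank:
                    b, child = single
                    p *= qp[pos] if b == seq[pos] else omqp[pos]
                    if p < p_min:
                        break
                    node = child
                    pos += 1
                    continue
                base = seq[pos]
                for b, child in children.items():
                    p2 = p * (qp[pos] if b == base else omqp[pos])
                    if p2 >= p_min:
                        stack.append((child, pos + 1, p2, budget))
                if in_flank:
                    pi = p * indel_penalty
                    if pi >= p_min:
                        # insertion in the read: consume a read base in place
                        stack.append((node, pos + 1, pi, budget - 1))
                        # deletion in the read: advance the reference only
                        for child in children.values():
                            stack.append((child, pos, pi, budget - 1))
                break
        return results


def build_primer_tree(primers) -> MatchTree:
    """Build the primer recognition tree with IUPAC degeneracy expanded.

    Two primers sharing an identical (sequence, direction) but different
    ids would make lookups ambiguous and are rejected.
    """
    primers = list(primers)
    if not primers:
        raise ValueError("primer library is empty")
    seen: dict[tuple[str, str], str] = {}
    for p in primers:
        key = (p.sequence.upper(), p.direction)
        if key in seen and seen[key] != p.id:
            raise ValueError(
                f"primers '{seen[key]}' and '{p.id}' share sequence "
                f"{p.sequence} ({p.direction}) with conflicting targets"
            )
        seen[key] = p.id
    return MatchTree.from_sequences(
        [(p.sequence, p.id) for p in primers], expand_iupac=True
    )
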