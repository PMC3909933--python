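"""Shared fixtures: tiny hand-built references and simulated ones."""

import numpy as np
import pytest

from exontyper.readio import QualityRead
from exontyper.reference import AlleleSequence, PrimerDef, ReferenceModel
from exontyper.simulate import SimulationConfig, simulate_reference


def make_read(seq, q=30, read_id="r1", mate=1, i1="", i2=""):
    if isinstance(q, int):
        quals = np.full(len(seq), q, dtype=np.uint8)
    else:
        quals = np.asarray(q, dtype=np.uint8)
    return QualityRead(read_id, mate, seq, quals, i1, i2)


@pytest.fixture(scope="session")
def sim_reference():
    """A 2-locus, 6-allele simulated reference (deterministic, seed 11)."""
    cfg = SimulationConfig(
        seed=11, n_loci=2, alleles_per_locus=6, pairwise_divergence=6
    )
    return cfg, simulate_reference(cfg)


@pytest.fixture(scope="session")
def sim_model(sim_reference):
    cfg, ref = sim_reference
    return cfg, ref, ReferenceModel(ref.alleles, ref.primers, read_length=cfg.read_length)


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def qp(q: float) -> float:
    return 1.0 - 10.0 ** (-q / 10.0)


def brute_force_match_probs(seq, quals, candidates, p_min):
    """Per-candidate product of Q_p / (1−Q_p) factors over the covered span.

    ``candidates``: list of (payload, reference sequence).  IUPAC codes in
    the reference count as agreement when the read base is in their set.
    Only products ≥ p_min are reported (mirroring walk pruning).
    """
    from exontyper.trie import IUPAC

    out = {}
    for payload, ref in candidates:
        p = 1.0
        for i in range(min(len(seq), len(ref))):
            agree = seq[i] in IUPAC.get(ref[i], ref[i])
            f = qp(quals[i]) if agree else 1.0 - qp(quals[i])
            p *= f
        if p >= p_min:
            out[payload] = max(out.get(payload, 0.0), p)
    return out


def exact_binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X ≥ k) for X ~ Binomial(n, p) in exact rational arithmetic.

    Sums the k lower-tail terms as Fractions (p taken at its exact binary
    value) and complements, so the only rounding is the final float cast.
    """
    import math
    from fractions import Fraction

    if k <= 0:
        return 1.0
    pf = Fraction(p)
    qf = 1 - pf
    lower = sum(
        math.comb(n, j) * pf ** j * qf ** (n - j) for j in range(k)
    )
    return float(1 - lower)


def pairwise_equality_partition(items):
    """O(n²) grouping of (name, key) pairs by all-pairs key equality."""
    groups = []
    for name, key in items:
        for g in groups:
            if g["key"] == key:
                g["members"].add(name)
                break
        else:
            groups.append({"key": key, "members": {name}})
    return sorted((frozenset(g["members"]) for g in groups), key=min)
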