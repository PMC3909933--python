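"""Paired-end FASTQ input, dual-index validation and sample demultiplexing.

Reads arrive as synchronized R1/R2 FASTQ files (Phred+33).  The 8+8-base
dual index of each cluster is taken either from separate I1/I2 FASTQ files
or, failing that, parsed from the read header (the ``INDEX1+INDEX2`` field
after the last colon).  A read pair is assigned to a sample only when both
indices match a sample-sheet row exactly (optionally tolerating one
mismatch per index); everything else lands in the unassigned bin with a
reason tag, so no read is ever silently dropped.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "QualityRead",
    "SampleSheet",
    "DemuxResult",
    "IndexSchemeReport",
    "FastqFormatError",
    "read_paired_fastq",
    "write_paired_fastq",
    "validate_index_scheme",
    "demultiplex",
]

INDEX_LENGTH = 8
_PHRED_OFFSET = 33


class FastqFormatError(ValueError):
    """Structural problem in a FASTQ stream (desync, bad quality encoding)."""


@dataclass(slots=True)
class QualityRead:
    """One sequencing read with per-base Phred qualities and its index pair.

    ``quals`` holds integer Phred scores (already Phred+33 decoded) as a
    ``uint8`` array of the same length as ``sequence``.
    """

    read_id: str
    mate: int
    sequence: str
    quals: np.ndarray
    index1: str = ""
    index2: str = ""

    def validate(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        if len(self.quals) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: {len(self.quals)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if len(self.quals) and (self.quals.max() > 60):
            raise ValueError(f"read {self.read_id}: Phred score above 60")
        for idx in (self.index1, self.index2):
            if idx and len(idx) != INDEX_LENGTH:
                raise ValueError(
                    f"read {self.read_id}: index '{idx}' is not {INDEX_LENGTH} bases"
                )

    @property
    def qual_string(self) -> str:
        return (self.quals + _PHRED_OFFSET).tobytes().decode("ascii")


def _decode_quals(qual_str: str, record_id: str, line_hint: int) -> np.ndarray:
    raw = qual_str.encode("ascii", errors="replace")
    arr = np.frombuffer(raw, dtype=np.uint8)
    if arr.size and (arr.min() < _PHRED_OFFSET or arr.max() > 126):
        raise FastqFormatError(
            f"non-ASCII or out-of-range quality character in record "
            f"'{record_id}' (around line {line_hint})"
        )
    return arr - _PHRED_OFFSET


def _open_text(path) -> io.TextIOBase:
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _parse_header_indices(title: str) -> tuple[str, str]:
    # Illumina-style: "<id> <run info>:<...>:INDEX1+INDEX2"
    tail = title.rsplit(":", 1)[-1].strip()
    if "+" in tail:
        i1, _, i2 = tail.partition("+")
        return i1.strip(), i2.strip()
    return "", ""


def _base_id(title: str) -> str:
    # strip mate suffix ("/1") and comment
    head = title.split()[0] if title.split() else title
    if head.endswith("/1") or head.endswith("/2"):
        head = head[:-2]
    return head


def read_paired_fastq(
    r1,
    r2,
    i1=None,
    i2=None,
) -> Iterator[tuple[QualityRead, QualityRead]]:
    """Stream mate-paired reads from synchronized FASTQ files.

    Indices come from the I1/I2 files when given (their sequence lines),
    otherwise from the header field after the last colon.
    """
    h1, h2 = _open_text(r1), _open_text(r2)
    hi1 = _open_text(i1) if i1 is not None else None
    hi2 = _open_text(i2) if i2 is not None else None
    it1 = FastqGeneralIterator(h1)
    it2 = FastqGeneralIterator(h2)
    iti1 = FastqGeneralIterator(hi1) if hi1 else None
    iti2 = FastqGeneralIterator(hi2) if hi2 else None
    try:
        n = 0
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2):
            n += 1
            id1, id2 = _base_id(t1), _base_id(t2)
            if id1 != id2:
                raise FastqFormatError(
                    f"R1/R2 desynchronized at record {n}: '{id1}' vs '{id2}'"
                )
            if iti1 is not None and iti2 is not None:
                try:
                    (_, si1, _), (_, si2, _) = next(iti1), next(iti2)
                except StopIteration:
                    raise FastqFormatError(
                        f"index FASTQ shorter than read FASTQ at record {n}"
                    ) from None
                ix1, ix2 = si1.strip(), si2.strip()
            else:
                ix1, ix2 = _parse_header_indices(t1)
            line = 4 * n
            yield (
                QualityRead(id1, 1, s1.upper(), _decode_quals(q1, id1, line), ix1, ix2),
                QualityRead(id2, 2, s2.upper(), _decode_quals(q2, id2, line), ix1, ix2),
            )
    finally:
        for h in (h1, h2, hi1, hi2):
            if h is not None:
                h.close()


def write_paired_fastq(
    pairs: Iterable[tuple[QualityRead, QualityRead]],
    r1_path,
    r2_path,
) -> int:
    """Write mate pairs to two FASTQ files, embedding indices in headers."""
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rd1, rd2 in pairs:
            for rd, fh in ((rd1, f1), (rd2, f2)):
                fh.write(
                    f"@{rd.read_id} {rd.mate}:N:0:{rd.index1}+{rd.index2}\n"
                    f"{rd.sequence}\n+\n{rd.qual_string}\n"
                )
            n += 1
    return n


# ---------------------------------------------------------------------------
# sample sheet and index scheme
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Sample ↔ dual-index assignment table."""

    rows: pd.DataFrame  # columns: sample_id, index1, index2, chip_id

    COLUMNS = ("sample_id", "index1", "index2", "chip_id")

    def __post_init__(self) -> None:
        for col in self.COLUMNS[:3]:
            if col not in self.rows.columns:
                raise ValueError(f"sample sheet is missing column '{col}'")
        if "chip_id" not in self.rows.columns:
            self.rows = self.rows.assign(chip_id="")
        dup = self.rows.duplicated(subset=["index1", "index2"])
        if dup.any():
            bad = self.rows.loc[dup, ["index1", "index2"]].iloc[0]
            raise ValueError(
                f"duplicate index combination {bad.index1}+{bad.index2} in sample sheet"
            )
        if self.rows["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "SampleSheet":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)[: len(records[0])]))

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.rows)

    def combination_map(self) -> dict[tuple[str, str], str]:
        return {
            (r.index1, r.index2): r.sample_id for r in self.rows.itertuples(index=False)
        }


@dataclass(slots=True)
class IndexSchemeReport:
    n_index1: int
    n_index2: int
    n_combinations: int
    n_used: int
    n_unused: int
    unused_fraction: float
    missing_indices: list[str] = field(default_factory=list)


def validate_index_scheme(
    index1_list: Sequence[str],
    index2_list: Sequence[str],
    samplesheet: SampleSheet,
) -> IndexSchemeReport:
    """Check the dual-index space against the sample sheet.

    With 96 index1 and 16 index2 sequences the space holds 1536 unique
    combinations, of which a 384-sample run uses one quarter; the unused
    three quarters act as a sink for index-hopped pairs.
    """
    for name, lst in (("index1", index1_list), ("index2", index2_list)):
        seen: set[str] = set()
        for ix in lst:
            if ix in seen:
                raise ValueError(f"duplicate {name} sequence '{ix}'")
            seen.add(ix)
    n_comb = len(index1_list) * len(index2_list)
    n_used = len(samplesheet)
    missing = []
    s1, s2 = set(index1_list), set(index2_list)
    for r in samplesheet.rows.itertuples(index=False):
        if r.index1 not in s1:
            missing.append(f"index1:{r.index1}")
        if r.index2 not in s2:
            missing.append(f"index2:{r.index2}")
    return IndexSchemeReport(
        n_index1=len(index1_list),
        n_index2=len(index2_list),
        n_combinations=n_comb,
        n_used=n_used,
        n_unused=n_comb - n_used,
        unused_fraction=(n_comb - n_used) / n_comb if n_comb else 0.0,
        missing_indices=missing,
    )


@dataclass
class DemuxResult:
    """Per-sample read-pair bins plus the unassigned bin with reason tags."""

    by_sample: dict[str, list[tuple[QualityRead, QualityRead]]]
    unassigned: list[tuple[tuple[QualityRead, QualityRead], str]]
    n_total: int

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(p) for s, p in self.by_sample.items()}

    @property
    def n_assigned(self) -> int:
        return sum(len(p) for p in self.by_sample.values())

    def report(self) -> pd.DataFrame:
        total = max(self.n_total, 1)
        rows = [
            {"sample_id": s, "n_pairs": len(p), "fraction": len(p) / total}
            for s, p in sorted(self.by_sample.items())
        ]
        rows.append(
            {
                "sample_id": "__unassigned__",
                "n_pairs": len(self.unassigned),
                "fraction": len(self.unassigned) / total,
            }
        )
        return pd.DataFrame(rows)


def _within_one_mismatch(ix: str, pool: set[str]) -> Optional[str]:
    if ix in pool:
        return ix
    for cand in pool:
        if len(cand) == len(ix) and sum(a != b for a, b in zip(cand, ix)) <= 1:
            return cand
    return None


def demultiplex(
    reads: Iterable[tuple[QualityRead, QualityRead]],
    samplesheet: SampleSheet,
    index1_pool: Optional[Sequence[str]] = None,
    index2_pool: Optional[Sequence[str]] = None,
    index_mismatches: int = 0,
) -> DemuxResult:
    """Assign read pairs to samples by exact dual-index match.

    A pair whose combination exists in the full index space but not in the
    sample sheet is tagged ``unused_combination`` — the deliberate sink for
    index hopping; combinations involving an unknown index are tagged
    ``unknown_index``.
    """
    combo = samplesheet.combination_map()
    sheet1 = {r.index1 for r in samplesheet.rows.itertuples(index=False)}
    sheet2 = {r.index2 for r in samplesheet.rows.itertuples(index=False)}
    pool1 = set(index1_pool) if index1_pool is not None else None
    pool2 = set(index2_pool) if index2_pool is not None else None
    by_sample: dict[str, list] = {
        r.sample_id: [] for r in samplesheet.rows.itertuples(index=False)
    }
    unassigned: list[tuple[tuple[QualityRead, QualityRead], str]] = []
    n_total = 0
    for pair in reads:
        n_total += 1
        i1, i2 = pair[0].index1, pair[0].index2
        if index_mismatches >= 1:
            c1 = _within_one_mismatch(i1, pool1 or sheet1)
            c2 = _within_one_mismatch(i2, pool2 or sheet2)
            key = (c1 or i1, c2 or i2)
        else:
            key = (i1, i2)
        sample = combo.get(key)
        if sample is not None:
            by_sample[sample].append(pair)
            continue
        in_space = (
            pool1 is not None
            and pool2 is not None
            and key[0] in pool1
            and key[1] in pool2
        )
        unassigned.append((pair, "unused_combination" if in_space else "unknown_index"))
    return DemuxResult(by_sample=by_sample, unassigned=unassigned, n_total=n_total)
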