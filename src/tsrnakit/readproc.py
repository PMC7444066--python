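"""Small-RNA read processing.

The processing chain mirrors a standard small-RNA-seq workflow: 3' adapter
trimming, an inclusive length filter (default 12-50 nt), then hierarchical
annotation in which each read is tested against miRNA, then rRNA, then the
extended tRNA reference, keeping the first category that yields an ungapped
placement with at most ``max_mismatch`` mismatches. Reads surviving to the
tRNA step and placing there are the tsRNA candidates.

Alignment is a deterministic exhaustive ungapped scan rather than a
heuristic mapper: at the desk scales this package targets (tens of
references, thousands of reads) exhaustive placement is fast, reproducible
and directly checkable against a brute-force oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genes import normalize_rna
from .reference import MatureReference

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("miRNA", "rRNA", "tRNA")
MAX_N_FRACTION = 0.10


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read (post-basecalling, optionally with qualities)."""

    read_id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        # an empty sequence can only arise from adapter trimming; it is
        # kept representable so the length filter can discard it
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.read_id}: quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentHit:
    """A read's resolved category, and its placement when category is tRNA."""

    read_id: str
    category: str  # miRNA | rRNA | tRNA | unmapped
    ref_id: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    mismatches: int = 0


def read_fastq(path: str | Path) -> list[ReadRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        records.append(ReadRecord(rec.id, normalize_rna(str(rec.seq)), qual))
    return records


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")


def trim_adapter(read: ReadRecord, adapter: str) -> ReadRecord:
    """Remove a 3' adapter by exact prefix matching.

    If the full adapter occurs anywhere in the read, the read is truncated
    at its first occurrence. Otherwise the longest read suffix that equals
    an adapter prefix of length >= 6 is removed; reads with no such overlap
    are returned unchanged. An empty result (read == adapter) is returned
    as-is and is expected to be discarded by the length filter.
    """
    if len(adapter) < 6:
        raise ValueError(f"adapter must be >= 6 nt, got {len(adapter)}")
    adapter = normalize_rna(adapter)
    seq = read.seq
    cut = len(seq)
    idx = seq.find(adapter)
    if idx >= 0:
        cut = idx
    else:
        max_k = min(len(adapter) - 1, len(seq))
        for k in range(max_k, 5, -1):
            if seq.endswith(adapter[:k]):
                cut = len(seq) - k
                break
    if cut == len(seq):
        return read
    qual = read.qual[:cut] if read.qual is not None else None
    return ReadRecord(read.read_id, seq[:cut], qual)


def length_filter(reads: Iterable[ReadRecord], min_len: int = 12,
                  max_len: int = 50) -> list[ReadRecord]:
    """Keep reads with min_len <= length <= max_len (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= len(r.seq) <= max_len]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _UngappedIndex:
    """Exhaustive ungapped <=k-mismatch placement over a set of sequences."""

    def __init__(self, seqs: Mapping[str, str]):
        self.ids = sorted(seqs)
        self.seqs = {i: normalize_rna(seqs[i]) for i in self.ids}
        self.arrays = {i: _encode(self.seqs[i]) for i in self.ids}

    def best_hit(self, seq: str, max_mismatch: int
                 ) -> Optional[tuple[str, int, int]]:
        """Minimal-mismatch placement; ties broken by (ref_id, start).

        Returns (ref_id, start, mismatches) or None. Exact placements are
        resolved with a fast substring search; the mismatch scan only runs
        when no exact hit exists.
        """
        for rid in self.ids:
            pos = self.seqs[rid].find(seq)
            if pos >= 0:
                return rid, pos, 0
        if max_mismatch == 0:
            return None
        query = _encode(seq)
        m = len(query)
        best: Optional[tuple[int, str, int]] = None
        for rid in self.ids:
            ref = self.arrays[rid]
            n = len(ref) - m + 1
            if n <= 0:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref, m)
            mm = (windows != query).sum(axis=1)
            j = int(mm.argmin())
            if mm[j] <= max_mismatch:
                cand = (int(mm[j]), rid, j)
                if best is None or cand < best:
                    best = cand
        if best is None:
            return None
        mismatches, rid, start = best
        return rid, start, mismatches


def hierarchical_assign(reads: Sequence[ReadRecord],
                        mirna_ref: Mapping[str, str],
                        rrna_ref: Mapping[str, str],
                        trna_refs: Sequence[MatureReference],
                        max_mismatch: int = 1) -> list[AlignmentHit]:
    """Assign each read to the first category in which it places.

    Categories are tested in the fixed order miRNA -> rRNA -> tRNA; a read
    with any placement in an earlier category never reaches a later one.
    Reads with > 10% N are reported unmapped without being aligned. Every
    read receives exactly one hit.
    """
    if not mirna_ref or not rrna_ref or not trna_refs:
        raise ValueError("all three reference sets must be nonempty")
    indexes = [
        ("miRNA", _UngappedIndex(mirna_ref)),
        ("rRNA", _UngappedIndex(rrna_ref)),
        ("tRNA", _UngappedIndex({r.trna_id: r.extended_seq for r in trna_refs})),
    ]
    hits: list[AlignmentHit] = []
    for read in reads:
        seq = normalize_rna(read.seq)
        if seq.count("N") > MAX_N_FRACTION * len(seq):
            logger.warning("read %s: >10%% N, reported unmapped", read.read_id)
            hits.append(AlignmentHit(read.read_id, "unmapped"))
            continue
        placed = False
        for category, index in indexes:
            hit = index.best_hit(seq, max_mismatch)
            if hit is None:
                continue
            rid, start, mismatches = hit
            hits.append(AlignmentHit(read.read_id, category, rid,
                                     start, start + len(seq), mismatches))
            placed = True
            break
        if not placed:
            hits.append(AlignmentHit(read.read_id, "unmapped"))
    return hits


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: normalize_rna(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
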