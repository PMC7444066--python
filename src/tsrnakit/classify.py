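"""Six-class tRNA-fragment taxonomy.

Fragments of tRNA genes fall into six classes according to where their two
ends sit relative to the mature tRNA body and its anticodon loop:

* ``tRF-5`` / ``5p-half`` — anchored at the mature 5' end, ending before
  the anticodon loop (tRF-5) or inside it (5' half, the angiogenin-type
  cleavage product);
* ``tRF-3`` / ``3p-half`` — anchored at the 3' CCA end, starting after the
  anticodon loop (tRF-3) or inside it (3' half);
* ``i-tRF`` — wholly internal to the mature body;
* ``tRF-1`` — a fragment of the primary transcript's 3' trailer, starting
  at or immediately after the mature 3' end.

Fragments that straddle the mature/trailer boundary, and full-length
mature tRNAs, fit none of these shapes and are labelled ``unclassified``.

Two tolerances make the rules robust to ragged ends: ``end_tol`` (how far
a fragment terminus may sit from the reference terminus and still count as
anchored, default 1 nt) and ``loop_tol`` (how far beyond the annotated
anticodon loop a half's cleavage point may fall, default 3 nt; anticodon
stem positions cleave too, and on a canonical 76-nt body the documented
39-nt 3' half requires exactly this slack).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .plates import encode_license_plate
from .readproc import AlignmentHit
from .reference import MatureReference

CLASS_LABELS = ("tRF-5", "tRF-3", "i-tRF", "tRF-1", "5p-half", "3p-half")
UNCLASSIFIED = "unclassified"
ALL_LABELS = CLASS_LABELS + (UNCLASSIFIED,)

DEFAULT_END_TOL = 1
DEFAULT_LOOP_TOL = 3


@dataclass
class TsRNARecord:
    """A distinct fragment sequence with its classification and counts."""

    tsrna_seq: str
    license_plate: str
    parent_ids: list[str]
    class_label: str
    start: int
    end: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_label not in ALL_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.end - self.start != len(self.tsrna_seq):
            raise ValueError("interval length must equal sequence length")

    @property
    def length(self) -> int:
        return len(self.tsrna_seq)

    def total_count(self) -> int:
        return sum(self.counts.values())


def classify_fragment(hit: AlignmentHit, ref: MatureReference,
                      end_tol: int = DEFAULT_END_TOL,
                      loop_tol: int = DEFAULT_LOOP_TOL) -> str:
    """Classify one tRNA-placed fragment from its coordinates.

    ``hit.start``/``hit.end`` are on the extended reference. Rules are
    applied in a fixed order; the first that matches wins, and a fragment
    matching none (e.g. one straddling the CCA/trailer boundary, or the
    full-length mature tRNA) is ``unclassified``.
    """
    if hit.category != "tRNA":
        raise ValueError(f"hit {hit.read_id}: category {hit.category}, expected tRNA")
    start, end = hit.start, hit.end
    ext_len = len(ref.extended_seq)
    if start is None or end is None or not (0 <= start < end <= ext_len):
        raise ValueError(
            f"hit {hit.read_id}: interval [{start},{end}) outside [0,{ext_len}]")
    m = ref.trailer_start
    loop_s, loop_e = ref.landmarks.anticodon_loop
    w_lo, w_hi = loop_s - loop_tol, loop_e + loop_tol  # widened loop, half-open

    if start >= m - end_tol:
        return "tRF-1"
    if start <= end_tol and w_lo <= end < w_hi:
        return "5p-half"
    if start <= end_tol and end < w_lo:
        return "tRF-5"
    if end >= m - end_tol and w_lo <= start < w_hi:
        return "3p-half"
    if end >= m - end_tol and start >= w_hi:
        return "tRF-3"
    if start > end_tol and end < m - end_tol:
        return "i-tRF"
    return UNCLASSIFIED


def collapse_and_count(hits: Iterable[AlignmentHit],
                       refs: Sequence[MatureReference],
                       sample_id: str,
                       end_tol: int = DEFAULT_END_TOL,
                       loop_tol: int = DEFAULT_LOOP_TOL) -> list[TsRNARecord]:
    """Collapse identical fragment sequences into counted records.

    Each distinct sequence becomes one record: its count for ``sample_id``
    is the number of supporting reads, its class comes from its (first
    seen, deterministic) placement, and ``parent_ids`` lists every
    reference containing the sequence exactly.
    """
    by_id = {r.trna_id: r for r in refs}
    groups: dict[str, list[AlignmentHit]] = defaultdict(list)
    for hit in hits:
        if hit.category != "tRNA":
            raise ValueError(f"hit {hit.read_id}: category {hit.category}, expected tRNA")
        if hit.ref_id not in by_id:
            raise ValueError(f"hit {hit.read_id}: unknown reference {hit.ref_id}")
        seq = by_id[hit.ref_id].extended_seq[hit.start:hit.end]
        groups[seq].append(hit)
    records = []
    for seq in sorted(groups):
        group = sorted(groups[seq],
                       key=lambda h: (h.ref_id, h.start, h.read_id))
        lead = group[0]
        label = classify_fragment(lead, by_id[lead.ref_id], end_tol, loop_tol)
        parents = sorted(rid for rid, r in by_id.items()
                         if seq in r.extended_seq)
        records.append(TsRNARecord(
            tsrna_seq=seq,
            license_plate=encode_license_plate(seq),
            parent_ids=parents,
            class_label=label,
            start=lead.start,
            end=lead.end,
            counts={sample_id: len(group)},
        ))
    return records


def merge_records(per_sample: Mapping[str, Sequence[TsRNARecord]]
                  ) -> list[TsRNARecord]:
    """Merge per-sample record sets into one set with per-sample counts."""
    merged: dict[str, TsRNARecord] = {}
    for sample_id, records in per_sample.items():
        for rec in records:
            if rec.tsrna_seq not in merged:
                merged[rec.tsrna_seq] = TsRNARecord(
                    rec.tsrna_seq, rec.license_plate, list(rec.parent_ids),
                    rec.class_label, rec.start, rec.end, {})
            merged[rec.tsrna_seq].counts[sample_id] = \
                merged[rec.tsrna_seq].counts.get(sample_id, 0) \
                + rec.counts.get(sample_id, 0)
    return [merged[s] for s in sorted(merged)]
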