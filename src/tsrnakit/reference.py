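"""Extended mature tRNA references.

The small-RNA mapping database used throughout the package is built from
each tRNA gene by (i) removing intronic sequence, (ii) appending the
post-transcriptional CCA to the mature 3' end, and (iii) appending the
first 50 genomic nucleotides found 3' of the gene (the "trailer", the part
of the primary transcript that gives rise to tRF-1 fragments). Fragments
are therefore placed on a single coordinate system::

    [ mature body | CCA | 50-nt genomic trailer ]
    0          L     L+3                     L+53

``trailer_start`` = L+3 marks the first trailer base; landmark intervals
never extend past the mature body.

CCA is appended unconditionally, even when the gene happens to end in a
genomically encoded CCA; no deduplication is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genes import Landmarks, TRNAGeneModel

TRAILER_LENGTH = 50

_TSV_COLUMNS = [
    "trna_id", "trailer_start",
    "d_loop_start", "d_loop_end",
    "anticodon_loop_start", "anticodon_loop_end",
    "anticodon_start", "anticodon_end",
    "t_loop_start", "t_loop_end",
]


@dataclass(frozen=True)
class MatureReference:
    """A spliced mature tRNA with CCA and genomic trailer appended."""

    trna_id: str
    mature_seq: str
    trailer: str
    landmarks: Landmarks

    def __post_init__(self) -> None:
        if len(self.trailer) != TRAILER_LENGTH:
            raise ValueError(
                f"{self.trna_id}: trailer must be {TRAILER_LENGTH} nt, "
                f"got {len(self.trailer)}")
        self.landmarks.validate(len(self.mature_seq))

    @property
    def mature_cca_seq(self) -> str:
        return self.mature_seq + "CCA"

    @property
    def trailer_start(self) -> int:
        """First coordinate of the genomic trailer (= mature length + 3)."""
        return len(self.mature_seq) + 3

    @property
    def extended_seq(self) -> str:
        return self.mature_cca_seq + self.trailer


def build_mature_reference(gene: TRNAGeneModel) -> MatureReference:
    """Build the extended reference for one gene.

    Splices introns out, resolves strand to the mature sense, appends CCA
    unconditionally and takes the first 50 genomic nucleotides 3' of the
    gene as the trailer. Raises ``ValueError`` if the gene carries fewer
    than 50 nt of usable flank.
    """
    mature = gene.mature_sequence()
    trailer = gene.trailer_sequence(TRAILER_LENGTH)
    return MatureReference(gene.gene_id, mature, trailer, gene.landmarks)


def write_reference(refs: Sequence[MatureReference], fasta_path: str | Path,
                    landmarks_path: str | Path) -> None:
    """Write extended sequences to FASTA and landmarks to a TSV sidecar."""
    refs = list(refs)
    ids = [r.trna_id for r in refs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate reference ids: {dup}")
    records = [SeqRecord(Seq(r.extended_seq), id=r.trna_id, description="")
               for r in refs]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(landmarks_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for r in refs:
            lm = r.landmarks
            writer.writerow([
                r.trna_id, r.trailer_start,
                *lm.d_loop, *lm.anticodon_loop, *lm.anticodon, *lm.t_loop,
            ])


def read_reference(fasta_path: str | Path,
                   landmarks_path: str | Path) -> list[MatureReference]:
    """Inverse of :func:`write_reference`; validates every row."""
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    refs: list[MatureReference] = []
    seen: set[str] = set()
    with open(landmarks_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _TSV_COLUMNS:
            raise ValueError(f"landmark TSV line 1: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_TSV_COLUMNS):
                raise ValueError(f"landmark TSV line {lineno}: expected "
                                 f"{len(_TSV_COLUMNS)} fields, got {len(row)}")
            trna_id = row[0]
            if trna_id in seen:
                raise ValueError(f"landmark TSV line {lineno}: duplicate id {trna_id}")
            seen.add(trna_id)
            if trna_id not in seqs:
                raise ValueError(f"landmark TSV line {lineno}: id {trna_id} "
                                 "not present in FASTA")
            try:
                vals = [int(x) for x in row[1:]]
            except ValueError as exc:
                raise ValueError(f"landmark TSV line {lineno}: {exc}") from None
            trailer_start = vals[0]
            extended = seqs[trna_id]
            mature_len = trailer_start - 3
            if len(extended) != trailer_start + TRAILER_LENGTH or mature_len <= 0:
                raise ValueError(
                    f"landmark TSV line {lineno}: trailer_start {trailer_start} "
                    f"inconsistent with sequence length {len(extended)}")
            lm = Landmarks(
                d_loop=(vals[1], vals[2]),
                anticodon_loop=(vals[3], vals[4]),
                anticodon=(vals[5], vals[6]),
                t_loop=(vals[7], vals[8]),
            )
            try:
                ref = MatureReference(trna_id, extended[:mature_len],
                                      extended[trailer_start:], lm)
            except ValueError as exc:
                raise ValueError(f"landmark TSV line {lineno}: {exc}") from None
            if ref.mature_cca_seq != extended[:trailer_start]:
                raise ValueError(
                    f"landmark TSV line {lineno}: sequence at [{mature_len},"
                    f"{trailer_start}) is not CCA")
            refs.append(ref)
    missing = set(seqs) - seen
    if missing:
        raise ValueError(f"FASTA ids missing from landmark TSV: {sorted(missing)}")
    return refs


def reference_index(refs: Iterable[MatureReference]) -> dict[str, MatureReference]:
    return {r.trna_id: r for r in refs}
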