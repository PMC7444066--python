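"""tRNA gene models.

A :class:`TRNAGeneModel` describes a pre-tRNA gene locus: its exon
structure (with an optional intron between two exons), the anticodon, and
enough genomic sequence 3' of the gene to extract a trailer. Structural
landmarks (D-loop, anticodon loop, T-loop) are kept in spliced-mature
coordinates, i.e. on the intron-free tRNA body read 5'->3'.

Coordinates are 0-based, half-open throughout. ``genomic_seq`` is stored in
genome plus-strand orientation; for minus-strand genes the mature sense is
the reverse complement, resolved downstream at reference-build time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase and map U->T; the package works on the DNA alphabet."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class Landmarks:
    """Structural landmark intervals in spliced-mature coordinates.

    ``anticodon`` must sit inside ``anticodon_loop``; the three loops are
    ordered D-loop < anticodon loop < T-loop along the mature body.
    """

    d_loop: Interval
    anticodon_loop: Interval
    anticodon: Interval
    t_loop: Interval

    def validate(self, mature_len: int) -> None:
        for name, (s, e) in self.as_dict().items():
            if not (0 <= s < e <= mature_len):
                raise ValueError(
                    f"landmark {name}=[{s},{e}) outside mature range [0,{mature_len})"
                )
        if not (self.anticodon_loop[0] <= self.anticodon[0]
                and self.anticodon[1] <= self.anticodon_loop[1]):
            raise ValueError("anticodon interval must lie within the anticodon loop")
        if not (self.d_loop[1] <= self.anticodon_loop[0] < self.t_loop[0]
                and self.anticodon_loop[1] <= self.t_loop[0]):
            raise ValueError("landmarks must be ordered d_loop < anticodon_loop < t_loop")

    def as_dict(self) -> dict[str, Interval]:
        return {
            "d_loop": self.d_loop,
            "anticodon_loop": self.anticodon_loop,
            "anticodon": self.anticodon,
            "t_loop": self.t_loop,
        }


#: Canonical landmark geometry of a 76-nt mature tRNA body.
CANONICAL_LANDMARKS = Landmarks(
    d_loop=(13, 22),
    anticodon_loop=(31, 39),
    anticodon=(33, 36),
    t_loop=(53, 61),
)


@dataclass(frozen=True)
class TRNAGeneModel:
    """A pre-tRNA gene with genomic context.

    ``exons`` and ``intron`` are intervals on ``genomic_seq`` (plus-strand
    orientation); landmarks live in spliced-mature coordinates. The gene
    must carry at least 60 nt of genomic flank 3' of its last exon (in the
    mature sense) so that a 50-nt trailer can be appended downstream.
    """

    gene_id: str
    isotype: str
    anticodon: str
    strand: str
    exons: tuple[Interval, ...]
    intron: Optional[Interval]
    genomic_seq: str
    anticodon_mature_pos: Interval
    landmarks: Landmarks = field(default=CANONICAL_LANDMARKS)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if set(self.anticodon) - VALID_BASES or len(self.anticodon) != 3:
            raise ValueError(f"anticodon must be a 3-mer over ACGT, got {self.anticodon!r}")
        if not self.exons:
            raise ValueError("gene must have at least one exon")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.genomic_seq)):
                raise ValueError(f"exon [{s},{e}) outside genomic sequence")
            if s <= prev_end - 1 and prev_end >= 0 and s < prev_end:
                raise ValueError("exons must be disjoint and ordered")
            if s < prev_end:
                raise ValueError("exons must be disjoint and ordered")
            prev_end = e
        if self.intron is not None:
            if len(self.exons) < 2:
                raise ValueError("an intron requires at least two exons")
            s, e = self.intron
            if not any(self.exons[i][1] <= s and e <= self.exons[i + 1][0]
                       for i in range(len(self.exons) - 1)):
                raise ValueError("intron must lie strictly between two exons")
        self.landmarks.validate(self.spliced_length)
        (a_s, a_e) = self.anticodon_mature_pos
        (l_s, l_e) = self.landmarks.anticodon_loop
        if not (l_s <= a_s and a_e <= l_e):
            raise ValueError("anticodon_mature_pos must lie within the anticodon loop")
        if self.flank_length < 60:
            raise ValueError(
                f"gene {self.gene_id}: 3' genomic flank is {self.flank_length} nt, need >= 60"
            )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def flank_length(self) -> int:
        """Genomic nucleotides 3' of the gene in the mature sense."""
        if self.strand == "+":
            return len(self.genomic_seq) - self.exons[-1][1]
        return self.exons[0][0]

    def mature_sequence(self) -> str:
        """Spliced, strand-resolved mature body (no CCA)."""
        spliced = "".join(self.genomic_seq[s:e] for s, e in self.exons)
        return spliced if self.strand == "+" else revcomp(spliced)

    def trailer_sequence(self, length: int = 50) -> str:
        """Genomic trailer immediately 3' of the last exon, mature sense."""
        if self.flank_length < length:
            raise ValueError(
                f"gene {self.gene_id}: flank {self.flank_length} nt < trailer {length} nt"
            )
        if self.strand == "+":
            start = self.exons[-1][1]
            return self.genomic_seq[start:start + length]
        end = self.exons[0][0]
        return revcomp(self.genomic_seq[end - length:end])
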