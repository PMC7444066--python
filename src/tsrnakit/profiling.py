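"""Expression profiling summaries.

Summaries over classified fragment records and count matrices: fragment
length distributions, the tsRNA share of the total small-RNA library,
class-frequency breakdowns, positional coverage along parent tRNAs, and
reads-per-million normalization ("TPM" in the small-RNA sense: counts per
million mapped small-RNA reads, with no transcript-length correction —
discrete fragments are counted, not length-normalized).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ALL_LABELS, TsRNARecord
from .reference import MatureReference

logger = logging.getLogger(__name__)

STUDY_DAYS = frozenset({0, 7, 14, 21})


@dataclass
class CountMatrix:
    """tsRNA-by-sample counts with timepoint metadata.

    ``totals`` is the per-sample denominator for fraction computations:
    the total (post-filter) small-RNA reads in the sample, which is at
    least the tsRNA column sum.
    """

    counts: pd.DataFrame  # rows: plate ids, columns: sample ids
    sample_meta: pd.DataFrame  # index: sample ids; columns: day, replicate
    totals: pd.Series  # sample id -> total small-RNA reads
    allow_any_days: bool = False

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise ValueError("sample_meta index must match count columns")
        if list(self.counts.columns) != list(self.totals.index):
            raise ValueError("totals index must match count columns")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        colsums = self.counts.sum(axis=0)
        if (self.totals < colsums).any():
            bad = self.totals.index[self.totals < colsums].tolist()
            raise ValueError(f"totals below column sums for samples {bad}")
        if not self.allow_any_days:
            days = set(self.sample_meta["day"])
            if not days <= STUDY_DAYS:
                raise ValueError(
                    f"days {sorted(days - STUDY_DAYS)} outside the study "
                    f"timepoints {sorted(STUDY_DAYS)}; pass "
                    "allow_any_days=True to override")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for_day(self, day: int) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["day"] == day])

    def to_tsv(self, counts_path: str | Path, meta_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="plate_id")
        meta = self.sample_meta.copy()
        meta["total_reads"] = self.totals
        meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, meta_path: str | Path,
                 allow_any_days: bool = False) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="plate_id")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        totals = meta.pop("total_reads")
        return cls(counts=counts, sample_meta=meta, totals=totals,
                   allow_any_days=allow_any_days)


def records_to_matrix(records: Sequence[TsRNARecord],
                      sample_meta: pd.DataFrame,
                      totals: pd.Series,
                      allow_any_days: bool = False) -> CountMatrix:
    """Assemble classified records into a CountMatrix (rows sorted by id)."""
    rows = {}
    for rec in records:
        rows[rec.license_plate] = {
            s: rec.counts.get(s, 0) for s in sample_meta.index}
    counts = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=sample_meta.index).fillna(0).astype(int).sort_index()
    return CountMatrix(counts=counts, sample_meta=sample_meta,
                       totals=totals, allow_any_days=allow_any_days)


def length_histogram(records: Sequence[TsRNARecord], sample_id: str,
                     min_len: int = 12, max_len: int = 50
                     ) -> dict[int, float]:
    """Fragment-length distribution for one sample, as fractions of reads.

    Fractions sum to 1 over the observed lengths; lengths are restricted
    to the configured filter window. Empty samples yield an empty
    histogram (with a warning).
    """
    weights: dict[int, int] = {}
    for rec in records:
        n = rec.counts.get(sample_id, 0)
        if n and min_len <= rec.length <= max_len:
            weights[rec.length] = weights.get(rec.length, 0) + n
    total = sum(weights.values())
    if total == 0:
        logger.warning("sample %s: no tsRNA reads; empty histogram", sample_id)
        return {}
    return {length: weights[length] / total for length in sorted(weights)}


def tsrna_fraction(matrix: CountMatrix) -> dict[str, float]:
    """Per sample: fraction of total small-RNA reads that are tsRNAs."""
    out = {}
    colsums = matrix.counts.sum(axis=0)
    for sample in matrix.sample_ids:
        total = matrix.totals[sample]
        if total == 0:
            logger.warning("sample %s: zero total reads; fraction undefined",
                           sample)
            out[sample] = float("nan")
        else:
            out[sample] = float(colsums[sample] / total)
    return out


def class_fractions(records: Sequence[TsRNARecord], sample_id: str
                    ) -> dict[str, float]:
    """Per-class read fractions for one sample (sums to 1 over support)."""
    weights = {label: 0 for label in ALL_LABELS}
    for rec in records:
        weights[rec.class_label] += rec.counts.get(sample_id, 0)
    total = sum(weights.values())
    if total == 0:
        logger.warning("sample %s: no classified reads", sample_id)
        return {}
    return {label: w / total for label, w in weights.items() if w > 0}


def positional_coverage(records: Sequence[TsRNARecord],
                        ref: MatureReference
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Read-start and read-end depth along one extended reference.

    Counts every record whose parent list includes ``ref`` at its stored
    interval, weighted by its total count across samples. End depth is
    recorded at the last covered base (``end - 1``).
    """
    n = len(ref.extended_seq)
    start_depth = np.zeros(n, dtype=np.int64)
    end_depth = np.zeros(n, dtype=np.int64)
    for rec in records:
        if ref.trna_id in rec.parent_ids:
            weight = rec.total_count()
            start_depth[rec.start] += weight
            end_depth[rec.end - 1] += weight
    return start_depth, end_depth


def tpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million total small-RNA reads (no length correction)."""
    if (matrix.totals == 0).any():
        bad = matrix.totals.index[matrix.totals == 0].tolist()
        raise ValueError(f"zero total reads for samples {bad}")
    return matrix.counts.div(matrix.totals, axis=1) * 1e6


def plot_profile(records: Sequence[TsRNARecord], matrix: CountMatrix,
                 sample_ids: Optional[Iterable[str]] = None,
                 path: str | Path = "profile.png") -> None:
    """Three-panel summary figure: length histogram, class fractions,
    tsRNA share per sample."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = list(sample_ids) if sample_ids else matrix.sample_ids
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    for sample in samples:
        hist = length_histogram(records, sample)
        if hist:
            axes[0].plot(list(hist), list(hist.values()), marker="o",
                         label=sample)
    axes[0].set_xlabel("fragment length (nt)")
    axes[0].set_ylabel("fraction of tsRNA reads")
    axes[0].legend(fontsize=6)

    frac_table = pd.DataFrame(
        {s: class_fractions(records, s) for s in samples}).fillna(0).T
    frac_table.plot.bar(stacked=True, ax=axes[1], legend=True, fontsize=6)
    axes[1].set_ylabel("class fraction")

    fracs = tsrna_fraction(matrix)
    axes[2].bar(samples, [fracs[s] for s in samples])
    axes[2].set_ylabel("tsRNA fraction of total reads")
    for ax in axes:
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
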