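"""Synthetic data emulating a small-RNA-seq adipogenesis time course.

This module generates everything the downstream stages consume, so the
whole pipeline is testable without external downloads: toy tRNA gene
models with canonical cloverleaf landmarks, miRNA/rRNA contaminant
references, per-sample FASTQ read sets over the four differentiation
timepoints (days 0/7/14/21) with a read-level truth table, and
negative-binomial count matrices with planted differential expression.

The simulated experiment mirrors the profiled one: fragment lengths
concentrate in two modes (17-23 nt for tRFs, 30-36 nt for halves; 3'
halves necessarily run longer on a 76-nt body), all six fragment classes
are realizable, reads carry a 3' sequencing adapter, a configurable slice
of the library is miRNA/rRNA contamination, and overall tsRNA abundance
rises from day 0 to a day-7 peak. Quality strings are constant 'I';
sequencing error is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .genes import CANONICAL_LANDMARKS, Landmarks, TRNAGeneModel, revcomp
from .profiling import CountMatrix
from .reference import MatureReference, build_mature_reference

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
DAYS = (0, 7, 14, 21)

DEFAULT_CLASS_MIXTURE = {
    "tRF-5": 0.20,
    "tRF-3": 0.20,
    "i-tRF": 0.20,
    "tRF-1": 0.15,
    "5p-half": 0.15,
    "3p-half": 0.10,
}

#: Relative tsRNA abundance per day: rising from day 0 to a day-7 peak,
#: easing off through days 14 and 21, as in the profiled time course.
DEFAULT_TSRNA_SCALE = {0: 0.5, 7: 1.0, 14: 0.9, 21: 0.7}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def make_trna_gene(seed: int, isotype: str, anticodon: str,
                   with_intron: bool = False, strand: str = "+",
                   mature_len: int = 76,
                   landmarks: Landmarks = CANONICAL_LANDMARKS,
                   gene_id: Optional[str] = None) -> TRNAGeneModel:
    """Generate one toy pre-tRNA gene with canonical geometry.

    The mature body is random sequence of length ``mature_len`` (70-90
    allowed) carrying ``anticodon`` verbatim (5'->3' in the mature sense)
    at the anticodon landmark. With ``with_intron`` a 10-20 nt intron is
    inserted immediately 3' of mature position 37 (0-based: between
    positions 36 and 37 counted 1-based, i.e. after ``mature[:37]``),
    the canonical insertion point. The 3' flank is >= 60 nt and contains
    an oligo-T run (a pol III terminator) within 60 nt of the gene end.
    """
    anticodon = anticodon.upper().replace("U", "T")
    if len(anticodon) != 3 or set(anticodon) - set("ACGT"):
        raise ValueError(f"anticodon must be a 3-mer over ACGT, got {anticodon!r}")
    if not (70 <= mature_len <= 90):
        raise ValueError(f"mature_len must be in [70,90], got {mature_len}")
    rng = np.random.default_rng(seed)
    body = list(_random_seq(rng, mature_len))
    ac_s, ac_e = landmarks.anticodon
    body[ac_s:ac_e] = anticodon
    mature = "".join(body)

    if with_intron:
        intron_len = int(rng.integers(10, 21))
        intron_seq = _random_seq(rng, intron_len)
        gene_body = mature[:37] + intron_seq + mature[37:]
        exons = ((0, 37), (37 + intron_len, 37 + intron_len + mature_len - 37))
        intron = (37, 37 + intron_len)
    else:
        gene_body = mature
        exons = ((0, mature_len),)
        intron = None

    # flank: oligo-T terminator within 60 nt of the gene end
    pre = _random_seq(rng, int(rng.integers(8, 30))).replace("TTTT", "TTAT")
    run = "T" * int(rng.integers(4, 7))
    post = _random_seq(rng, 40)
    flank = (pre + run + post)[:70]
    if len(flank) < 60:
        flank = flank + _random_seq(rng, 60 - len(flank))

    genomic = gene_body + flank
    if strand == "-":
        total = len(genomic)
        genomic = revcomp(genomic)
        exons = tuple((total - e, total - s) for s, e in reversed(exons))
        if intron is not None:
            intron = (total - intron[1], total - intron[0])

    return TRNAGeneModel(
        gene_id=gene_id or f"tRNA-{isotype}-{anticodon}-{seed}",
        isotype=isotype,
        anticodon=anticodon,
        strand=strand,
        exons=exons,
        intron=intron,
        genomic_seq=genomic,
        anticodon_mature_pos=landmarks.anticodon,
        landmarks=landmarks,
    )


def make_gene_panel(seed: int, n_genes: int = 4) -> list[TRNAGeneModel]:
    """A small panel of distinct toy genes (mixed strands, one intronic)."""
    isotypes = [("Thr", "TGT"), ("Gly", "GCC"), ("Glu", "TTC"),
                ("Lys", "CTT"), ("Ala", "AGC"), ("Val", "CAC")]
    genes = []
    for i in range(n_genes):
        isotype, anticodon = isotypes[i % len(isotypes)]
        genes.append(make_trna_gene(
            seed=seed + i, isotype=isotype, anticodon=anticodon,
            with_intron=(i % 3 == 2), strand="-" if i % 4 == 3 else "+",
            gene_id=f"tRNA-{isotype}-{anticodon}-{i + 1}"))
    return genes


def make_contaminants(seed: int, n_mirna: int = 20, n_rrna: int = 2
                      ) -> tuple[dict[str, str], dict[str, str]]:
    """Random miRNA (21-23 nt) and rRNA (150 nt) contaminant references."""
    rng = np.random.default_rng(seed)
    mirna = {f"mir-{i + 1}": _random_seq(rng, int(rng.integers(21, 24)))
             for i in range(n_mirna)}
    rrna = {f"rRNA-{i + 1}": _random_seq(rng, 150) for i in range(n_rrna)}
    return mirna, rrna


@dataclass(frozen=True)
class PlantedFragment:
    """A specific fragment given day-dependent abundance (e.g. absent at
    day 0, peaking at day 7)."""

    ref_id: str
    class_label: str
    day_weights: dict[int, float]  # relative within-sample sampling weight


@dataclass
class SimulationProfile:
    """Configuration of one simulated sequencing experiment."""

    n_reads_per_sample: int = 5000
    class_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE))
    length_modes: tuple[tuple[int, int], tuple[int, int]] = ((17, 23), (30, 36))
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: {"miRNA": 0.10, "rRNA": 0.05})
    adapter: str = DEFAULT_ADAPTER
    planted_de: list[PlantedFragment] = field(default_factory=list)
    planted_fraction: float = 0.10
    tsrna_scale_by_day: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TSRNA_SCALE))
    days: tuple[int, ...] = DAYS
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in {**self.class_mixture,
                           **self.contaminant_fractions}.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction {name}={frac} outside [0,1]")
        if sum(self.class_mixture.values()) > 1.0 + 1e-9:
            raise ValueError("class mixture fractions must sum to <= 1")
        if not isinstance(self.replicates, int) or self.replicates < 1:
            raise ValueError(f"replicates must be a positive integer, "
                             f"got {self.replicates!r}")

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_reads_per_sample": self.n_reads_per_sample,
            "class_mixture": self.class_mixture,
            "length_modes": [list(m) for m in self.length_modes],
            "contaminant_fractions": self.contaminant_fractions,
            "adapter": self.adapter,
            "planted_de": [
                {"ref_id": p.ref_id, "class_label": p.class_label,
                 "day_weights": p.day_weights} for p in self.planted_de],
            "planted_fraction": self.planted_fraction,
            "tsrna_scale_by_day": self.tsrna_scale_by_day,
            "days": list(self.days),
            "replicates": self.replicates,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationProfile":
        data = yaml.safe_load(Path(path).read_text())
        data["length_modes"] = tuple(tuple(m) for m in data["length_modes"])
        data["days"] = tuple(data["days"])
        data["tsrna_scale_by_day"] = {
            int(k): float(v) for k, v in data["tsrna_scale_by_day"].items()}
        data["planted_de"] = [
            PlantedFragment(p["ref_id"], p["class_label"],
                            {int(k): float(v)
                             for k, v in p["day_weights"].items()})
            for p in data["planted_de"]]
        return cls(**data)


def _class_cut_range(ref: MatureReference, label: str,
                     modes: tuple[tuple[int, int], tuple[int, int]],
                     loop_tol: int = 3, end_tol: int = 1
                     ) -> Optional[tuple[int, int, int, int]]:
    """(start_lo, start_hi, len_lo, len_hi) for one class, or None.

    Cut positions are drawn so the resulting fragment is unambiguous under
    the classifier at default tolerances (non-boundary by construction).
    """
    m = ref.trailer_start
    loop_s, loop_e = ref.landmarks.anticodon_loop
    w_lo, w_hi = loop_s - loop_tol, loop_e + loop_tol
    (lo1, hi1), (lo2, hi2) = modes
    ext_len = len(ref.extended_seq)
    if label == "tRF-5":
        len_lo, len_hi = lo1, min(hi1, w_lo - 1)
        return (0, 0, len_lo, len_hi) if len_lo <= len_hi else None
    if label == "5p-half":
        len_lo, len_hi = max(lo2, w_lo), min(hi2, w_hi - 1)
        return (0, 0, len_lo, len_hi) if len_lo <= len_hi else None
    if label == "tRF-3":
        len_lo, len_hi = lo1, min(hi1, m - w_hi)
        return (-1, -1, len_lo, len_hi) if len_lo <= len_hi else None  # end = m
    if label == "3p-half":
        len_lo, len_hi = max(lo2, m - w_hi + 1), m - w_lo
        return (-1, -1, len_lo, len_hi) if len_lo <= len_hi else None
    if label == "i-tRF":
        len_lo, len_hi = lo1, min(hi1, m - end_tol - 3)
        return (2, -2, len_lo, len_hi) if len_lo <= len_hi else None
    if label == "tRF-1":
        len_lo, len_hi = lo1, min(hi1, ext_len - m)
        return (m, m, len_lo, len_hi) if len_lo <= len_hi else None
    raise ValueError(f"unknown class {label!r}")


def _draw_fragment(rng: np.random.Generator, ref: MatureReference, label: str,
                   modes: tuple[tuple[int, int], tuple[int, int]]
                   ) -> tuple[int, int]:
    rng_range = _class_cut_range(ref, label, modes)
    assert rng_range is not None
    start_lo, start_hi, len_lo, len_hi = rng_range
    length = int(rng.integers(len_lo, len_hi + 1))
    m = ref.trailer_start
    if start_lo == -1:  # 3' anchored
        start = m - length
    elif label == "i-tRF":
        start = int(rng.integers(2, m - 1 - length - 1))
    else:
        start = start_lo
    return start, start + length


def simulate_reads(refs: Sequence[MatureReference],
                   mirna_ref: dict[str, str], rrna_ref: dict[str, str],
                   profile: SimulationProfile
                   ) -> tuple[dict[str, list], pd.DataFrame]:
    """Simulate per-sample read sets with a read-level truth table.

    Returns ``(reads_by_sample, truth)``: a dict keyed by sample id
    (``d<day>_r<replicate>``) holding :class:`ReadRecord` lists, and a
    truth table with one row per read (read_id, sample_id, category,
    class_label, parent_id, start, end). Every tRNA-derived read is an
    exact substring of its parent's extended sequence, with the adapter
    appended.
    """
    from .readproc import ReadRecord

    mixture = {k: v for k, v in profile.class_mixture.items() if v > 0}
    for label in mixture:
        if not any(_class_cut_range(r, label, profile.length_modes)
                   for r in refs):
            raise ValueError(
                f"class {label!r} is unrealizable on every reference "
                f"with length modes {profile.length_modes}")
    realizable = {label: [r for r in refs
                          if _class_cut_range(r, label, profile.length_modes)]
                  for label in mixture}
    planted = [p for p in profile.planted_de]
    planted_frags: list[tuple[PlantedFragment, int, int]] = []
    rng = np.random.default_rng(profile.seed)
    ref_by_id = {r.trna_id: r for r in refs}
    for p in planted:
        ref = ref_by_id[p.ref_id]
        start, end = _draw_fragment(rng, ref, p.class_label,
                                    profile.length_modes)
        planted_frags.append((p, start, end))

    mix_labels = sorted(mixture)
    mix_probs = np.array([mixture[k] for k in mix_labels], dtype=float)
    mix_probs = mix_probs / mix_probs.sum()

    c_mi = profile.contaminant_fractions.get("miRNA", 0.0)
    c_rr = profile.contaminant_fractions.get("rRNA", 0.0)
    mirna_ids = sorted(mirna_ref)
    rrna_ids = sorted(rrna_ref)
    all_lens = list(range(profile.length_modes[0][0],
                          profile.length_modes[0][1] + 1)) + \
        list(range(profile.length_modes[1][0], profile.length_modes[1][1] + 1))

    reads_by_sample: dict[str, list] = {}
    truth_rows = []
    counter = 0
    for day in profile.days:
        scale = profile.tsrna_scale_by_day.get(day, 1.0)
        w_ts = (1.0 - c_mi - c_rr) * scale
        w = np.array([w_ts, c_mi, c_rr], dtype=float)
        cat_probs = w / w.sum()
        for rep in range(1, profile.replicates + 1):
            sample_id = f"d{day}_r{rep}"
            sample_reads = []
            for _ in range(profile.n_reads_per_sample):
                counter += 1
                read_id = f"read{counter:07d}"
                cat = ["tsRNA", "miRNA", "rRNA"][
                    int(rng.choice(3, p=cat_probs))]
                if cat == "miRNA":
                    rid = mirna_ids[int(rng.integers(len(mirna_ids)))]
                    body = mirna_ref[rid]
                    truth_rows.append((read_id, sample_id, "miRNA", "miRNA",
                                       rid, 0, len(body)))
                elif cat == "rRNA":
                    rid = rrna_ids[int(rng.integers(len(rrna_ids)))]
                    length = int(all_lens[int(rng.integers(len(all_lens)))])
                    start = int(rng.integers(0, len(rrna_ref[rid]) - length + 1))
                    body = rrna_ref[rid][start:start + length]
                    truth_rows.append((read_id, sample_id, "rRNA", "rRNA",
                                       rid, start, start + length))
                else:
                    use_planted = (planted_frags
                                   and rng.random() < profile.planted_fraction)
                    if use_planted:
                        weights = np.array(
                            [p.day_weights.get(day, 0.0)
                             for p, _, _ in planted_frags], dtype=float)
                        if weights.sum() > 0:
                            idx = int(rng.choice(len(planted_frags),
                                                 p=weights / weights.sum()))
                            p, start, end = planted_frags[idx]
                            ref = ref_by_id[p.ref_id]
                            body = ref.extended_seq[start:end]
                            truth_rows.append((read_id, sample_id, "tRNA",
                                               p.class_label, p.ref_id,
                                               start, end))
                            sample_reads.append(ReadRecord(
                                read_id, body + profile.adapter))
                            continue
                    label = mix_labels[int(rng.choice(len(mix_labels),
                                                      p=mix_probs))]
                    candidates = realizable[label]
                    ref = candidates[int(rng.integers(len(candidates)))]
                    start, end = _draw_fragment(rng, ref, label,
                                                profile.length_modes)
                    body = ref.extended_seq[start:end]
                    truth_rows.append((read_id, sample_id, "tRNA", label,
                                       ref.trna_id, start, end))
                sample_reads.append(ReadRecord(read_id, body + profile.adapter))
            reads_by_sample[sample_id] = sample_reads
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample_id", "category",
                             "class_label", "parent_id", "start", "end"])
    return reads_by_sample, truth


def write_simulation(reads_by_sample: dict, truth: pd.DataFrame,
                     outdir: str | Path) -> None:
    """Write one FASTQ per sample plus the truth TSV."""
    from .readproc import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample_id, reads in reads_by_sample.items():
        write_fastq(reads, outdir / f"{sample_id}.fastq")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


DEFAULT_DISPERSION = 0.02


def simulate_count_experiment(n_tsrna: int, n_de: int, effect: float,
                              base_mean: float, replicates: int, seed: int,
                              dispersion: float = DEFAULT_DISPERSION,
                              mode: str = "fold",
                              days: tuple[int, int] = (0, 7)
                              ) -> tuple[CountMatrix, pd.Series]:
    """Simulate a tsRNA count matrix with planted differential expression.

    Exactly ``n_de`` rows differ between the two day groups by a true fold
    change of ``effect``; the rest have identical means. ``mode="fold"``
    sets group means (base_mean, base_mean * effect); ``mode=
    "absent-then-peak"`` sets them (0, base_mean * effect), mimicking
    fragments undetectable at day 0 that peak at day 7. Counts are drawn
    from a negative binomial with variance mu + dispersion * mu**2
    (Poisson when dispersion = 0). Row ids are license plates of random
    fragment sequences. Returns the matrix and a boolean truth series.
    """
    if not isinstance(replicates, int) or replicates < 1:
        raise ValueError(f"replicates must be a positive integer, got {replicates!r}")
    if base_mean < 0 or effect < 1 and n_de > 0:
        raise ValueError("base_mean must be >= 0 and effect >= 1 for planted DE")
    if n_de > n_tsrna:
        raise ValueError(f"n_de {n_de} > n_tsrna {n_tsrna}")
    if mode not in ("fold", "absent-then-peak"):
        raise ValueError(f"unknown mode {mode!r}")
    from .plates import encode_license_plate

    rng = np.random.default_rng(seed)
    plates: list[str] = []
    seen = set()
    while len(plates) < n_tsrna:
        seq = _random_seq(rng, int(rng.integers(18, 41)))
        if seq not in seen:
            seen.add(seq)
            plates.append(encode_license_plate(seq))
    de_flags = np.zeros(n_tsrna, dtype=bool)
    de_flags[:n_de] = effect > 1
    low = 0.0 if mode == "absent-then-peak" else base_mean
    mean_a = np.where(de_flags, low, base_mean)
    mean_b = np.where(de_flags, base_mean * effect, base_mean)

    def draw(mu: np.ndarray) -> np.ndarray:
        out = np.zeros(len(mu), dtype=np.int64)
        pos = mu > 0
        if dispersion > 0:
            size = 1.0 / dispersion
            p = size / (size + mu[pos])
            out[pos] = rng.negative_binomial(size, p)
        else:
            out[pos] = rng.poisson(mu[pos])
        return out

    day_a, day_b = days
    columns, data, meta_rows = [], [], []
    for day, mu in ((day_a, mean_a), (day_b, mean_b)):
        for rep in range(1, replicates + 1):
            columns.append(f"d{day}_r{rep}")
            data.append(draw(mu))
            meta_rows.append((f"d{day}_r{rep}", day, rep))
    counts = pd.DataFrame(np.column_stack(data), index=plates, columns=columns)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "day", "replicate"]
                        ).set_index("sample_id")
    totals = counts.sum(axis=0)
    matrix = CountMatrix(counts=counts, sample_meta=meta, totals=totals)
    truth = pd.Series(de_flags, index=plates, name="is_de")
    return matrix, truth
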