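"""miRNA-style target-site scanning of 3'-UTRs.

A small RNA binds a messenger UTR antiparallel, so candidate sites are
found by locally aligning the small RNA (5'->3') against the reverse
complement of the UTR: an aligned identity is a Watson-Crick pair, and in
this orientation the G:U wobble pairs (small-RNA G with UTR U, small-RNA
U with UTR G) appear as the mismatch patterns G/A and T/C.

Scoring is an affine-gap local alignment with Watson-Crick match +5,
wobble +1, mismatch -3, gap open -8, gap extend -2, with scores doubled
at small-RNA positions 2-8 (the seed, whose pairing dominates targeting).
Sites with score >= a threshold (default 80) are reported non-overlapping,
best first. Each site carries a duplex-stability proxy, the negative of
(3 x GC pairs + 2 x AT pairs + 1 x GU pairs) over the paired columns —
more negative is more stable; it is a pairing-strength tally, not a free
energy.

``mutate_site`` produces the matched mutant UTR for reporter-style
comparisons: it substitutes paired seed positions to the base that
abolishes pairing outright (neither complement nor wobble partner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genes import normalize_rna, revcomp

NEG_INF = float("-inf")

_WOBBLE_RC = {("G", "A"), ("T", "C")}  # (small-RNA base, revcomp-UTR base)


@dataclass(frozen=True)
class ScanParams:
    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_weight: float = 2.0
    seed_start: int = 1  # 0-based; positions 2-8 in 1-based seed convention
    seed_end: int = 8
    threshold: float = 80.0


@dataclass
class TargetSite:
    """One predicted binding site on a UTR."""

    utr_id: str
    site_interval: tuple[int, int]  # on the UTR, 0-based half-open
    score: float
    stability_proxy: float
    pairing_string: str  # one symbol per alignment column: | o x -
    seed_matched: bool
    #: aligned columns as (small-RNA index, UTR index, symbol); gap columns
    #: carry None on the unaligned side
    columns: list[tuple[Optional[int], Optional[int], str]] = field(
        default_factory=list, repr=False)


def _pair_symbol(s_base: str, t_base: str) -> str:
    if s_base == t_base:
        return "|"
    if (s_base, t_base) in _WOBBLE_RC:
        return "o"
    return "x"


def _position_weight(i: int, params: ScanParams) -> float:
    return params.seed_weight if params.seed_start <= i < params.seed_end else 1.0


def _substitution(s_base: str, t_base: str, i: int, params: ScanParams) -> float:
    symbol = _pair_symbol(s_base, t_base)
    base = {"|": params.match, "o": params.wobble, "x": params.mismatch}[symbol]
    return base * _position_weight(i, params)


def perfect_score(tsrna_seq: str, params: ScanParams = ScanParams()) -> float:
    """Score of a full-length perfect Watson-Crick duplex (the optimum)."""
    seq = normalize_rna(tsrna_seq)
    return sum(params.match * _position_weight(i, params)
               for i in range(len(seq)))


def _smith_waterman(query: str, target: str, params: ScanParams,
                    banned: np.ndarray) -> tuple[float, Optional[tuple]]:
    """Affine-gap local alignment; target columns where ``banned`` is True
    cannot be aligned or skipped through. Returns (best score, traceback
    info) with traceback as (end_i, end_j, pointer matrices)."""
    m, n = len(query), len(target)
    M = [[0.0] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in target
    Iy = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in query
    ptr_m = [[0] * (n + 1) for _ in range(m + 1)]  # 0 start, 1 M, 2 Ix, 3 Iy
    ptr_x = [[0] * (n + 1) for _ in range(m + 1)]  # 1 from M, 2 extend
    ptr_y = [[0] * (n + 1) for _ in range(m + 1)]
    gap_open, gap_extend = params.gap_open, params.gap_extend
    best, best_pos = 0.0, None
    for i in range(1, m + 1):
        qi = query[i - 1]
        m_up, ix_up = M[i - 1], Ix[i - 1]
        iy_up = Iy[i - 1]
        m_row, ix_row, iy_row = M[i], Ix[i], Iy[i]
        pm_row, px_row, py_row = ptr_m[i], ptr_x[i], ptr_y[i]
        for j in range(1, n + 1):
            if banned[j - 1]:
                m_row[j] = 0.0
                ix_row[j] = iy_row[j] = NEG_INF
                continue
            sub = _substitution(qi, target[j - 1], i - 1, params)
            open_x = m_up[j] + gap_open
            ext_x = ix_up[j] + gap_extend
            if open_x >= ext_x:
                ix_row[j], px_row[j] = open_x, 1
            else:
                ix_row[j], px_row[j] = ext_x, 2
            open_y = m_row[j - 1] + gap_open
            ext_y = iy_row[j - 1] + gap_extend
            if open_y >= ext_y:
                iy_row[j], py_row[j] = open_y, 1
            else:
                iy_row[j], py_row[j] = ext_y, 2
            d_m, d_x, d_y = m_up[j - 1], ix_up[j - 1], iy_up[j - 1]
            if d_m >= d_x and d_m >= d_y:
                prev_best, k = d_m, 1
            elif d_x >= d_y:
                prev_best, k = d_x, 2
            else:
                prev_best, k = d_y, 3
            diag = prev_best + sub
            if diag <= 0:
                m_row[j], pm_row[j] = 0.0, 0
            else:
                m_row[j], pm_row[j] = diag, k
            if m_row[j] > best:
                best, best_pos = m_row[j], (i, j)
    return best, (best_pos, M, Ix, Iy, ptr_m, ptr_x, ptr_y)


def _traceback(query: str, target: str, params: ScanParams,
               tb) -> tuple[list, int, int]:
    (end_i, end_j), M, Ix, Iy, ptr_m, ptr_x, ptr_y = tb[0], *tb[1:]
    columns = []
    i, j, state = end_i, end_j, "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i][j] <= 0:
                break
            sym = _pair_symbol(query[i - 1], target[j - 1])
            columns.append((i - 1, j - 1, sym))
            prev = ptr_m[i][j]
            i, j = i - 1, j - 1
            if prev == 0:
                break
            state = ("M", "Ix", "Iy")[prev - 1]
        elif state == "Ix":
            columns.append((i - 1, None, "-"))
            prev = ptr_x[i][j]
            i -= 1
            state = "M" if prev == 1 else "Ix"
        else:
            columns.append((None, j - 1, "-"))
            prev = ptr_y[i][j]
            j -= 1
            state = "M" if prev == 1 else "Iy"
    columns.reverse()
    j_start = min(c[1] for c in columns if c[1] is not None)
    j_end = max(c[1] for c in columns if c[1] is not None) + 1
    return columns, j_start, j_end


def scan_utr(tsrna_seq: str, utr_seq: str, utr_id: str = "utr",
             params: ScanParams = ScanParams()) -> list[TargetSite]:
    """Scan one UTR for tsRNA binding sites.

    Returns non-overlapping sites with score >= ``params.threshold``,
    sorted best-first. Site intervals are in UTR coordinates (0-based,
    half-open, on the UTR's own strand).
    """
    query = normalize_rna(tsrna_seq)
    utr = normalize_rna(utr_seq)
    for name, seq in (("tsRNA", query), ("UTR", utr)):
        if set(seq) - set("ACGT"):
            raise ValueError(f"{name} sequence contains non-ACGT characters")
    if not (12 <= len(query) <= 50):
        raise ValueError(f"tsRNA length {len(query)} outside [12,50]")
    target = revcomp(utr)
    banned = np.zeros(len(target), dtype=bool)
    sites: list[TargetSite] = []
    while True:
        score, tb = _smith_waterman(query, target, params, banned)
        if score < params.threshold or tb[0] is None:
            break
        columns, j_start, j_end = _traceback(query, target, params, tb)
        banned[j_start:j_end] = True
        # map revcomp coordinates back to the UTR strand
        utr_interval = (len(utr) - j_end, len(utr) - j_start)
        paired = [(qi, tj, sym) for qi, tj, sym in columns
                  if qi is not None and tj is not None]
        gc = sum(1 for qi, _, sym in paired
                 if sym == "|" and query[qi] in "GC")
        at = sum(1 for qi, _, sym in paired
                 if sym == "|" and query[qi] in "AT")
        gu = sum(1 for _, _, sym in paired if sym == "o")
        seed_positions = set(range(params.seed_start,
                                   min(params.seed_end, len(query))))
        matched = {qi for qi, _, sym in paired if sym == "|"}
        sites.append(TargetSite(
            utr_id=utr_id,
            site_interval=utr_interval,
            score=float(score),
            stability_proxy=-(3.0 * gc + 2.0 * at + 1.0 * gu),
            pairing_string="".join(sym for _, _, sym in columns),
            seed_matched=seed_positions <= matched,
            columns=columns,
        ))
    sites.sort(key=lambda s: (-s.score, s.site_interval))
    return sites


def mutate_site(utr_seq: str, tsrna_seq: str, site: TargetSite,
                n_mut: int = 4, seed: int = 0) -> str:
    """Mutate ``n_mut`` paired seed positions of a site in the UTR.

    Substitutions target the Watson-Crick-paired columns whose small-RNA
    index lies in the seed, replacing the UTR base with the unique base
    that is neither the complement nor the wobble partner of the small-RNA
    base (maximal score loss: match -> mismatch with no wobble rescue).
    The UTR length is unchanged. Positions are chosen reproducibly from
    ``seed`` when more are available than needed.
    """
    query = normalize_rna(tsrna_seq)
    utr = list(normalize_rna(utr_seq))
    params = ScanParams()
    seed_cols = [(qi, tj) for qi, tj, sym in site.columns
                 if sym == "|" and qi is not None and tj is not None
                 and params.seed_start <= qi < params.seed_end]
    if n_mut > len(seed_cols):
        raise ValueError(
            f"n_mut={n_mut} exceeds the {len(seed_cols)} paired seed positions")
    if n_mut == 0:
        return "".join(utr)
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(seed_cols), size=n_mut, replace=False))
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    wobble_partner = {"G": "T", "T": "G"}  # on the UTR strand
    for k in chosen:
        qi, tj = seed_cols[k]
        utr_pos = len(utr) - 1 - tj  # revcomp coordinate -> UTR coordinate
        q_base = query[qi]
        forbidden = {complement[q_base], wobble_partner.get(q_base, "")}
        candidates = [b for b in "ACGT"
                      if b not in forbidden and b != utr[utr_pos]]
        utr[utr_pos] = candidates[int(rng.integers(len(candidates)))]
    return "".join(utr)
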