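"""Differential tsRNA expression between timepoints.

The calling layer applies the study cut-offs — fold change > 2 or < 0.5
(equivalently |log2FC| > 1), p < 0.05 and Benjamini-Hochberg FDR < 0.05 —
on top of a deliberately simple, assumption-light count test:

* size factors by the median-of-ratios method (falling back to library
  totals when no row is positive in every sample);
* per-row fold changes from normalized group means with a pseudocount;
* a two-sided exact conditional binomial test on the row's summed raw
  counts: conditional on the row total, the group-B share is binomial
  with success probability equal to group B's share of the summed library
  sizes under the null of equal relative abundance.

The conditional binomial test is exact under Poisson-level count
variation (conditioning a Poisson pair on its sum gives a binomial); it
does not absorb extra biological overdispersion across replicates — see
the methods notes for the implications.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiling import CountMatrix

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["plate_id", "mean_a", "mean_b", "log2fc",
                  "p_value", "fdr", "significant"]


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    Rows with a zero in any sample are excluded from the median. If no row
    is positive everywhere, falls back to column-total (per-million style)
    factors, with a log message.
    """
    counts = matrix.counts
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) == 0:
        logger.warning("no row positive in all samples; falling back to "
                       "column-total size factors")
        factors = counts.sum(axis=0).astype(float)
        if (factors == 0).any():
            raise ValueError("cannot derive size factors: empty library")
    else:
        log_geo = np.log(positive).mean(axis=1)
        ratios = np.log(positive).sub(log_geo, axis=0)
        factors = np.exp(ratios.median(axis=0))
    factors = factors / np.exp(np.log(factors).mean())
    return factors


def de_test(matrix: CountMatrix, group_a: Sequence[str],
            group_b: Sequence[str], pseudocount: float = 1.0
            ) -> pd.DataFrame:
    """Per-row differential test of group B over group A.

    Returns a DataFrame with normalized group means, log2 fold change
    (pseudocount-stabilized), exact conditional binomial p-values and BH
    FDR. The ``significant`` column is filled at the default cut-offs;
    use :func:`call_significant` to re-threshold.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    missing = [s for s in group_a + group_b if s not in matrix.counts.columns]
    if missing:
        raise ValueError(f"unknown samples {missing}")
    lib = matrix.counts.sum(axis=0).astype(float)
    if lib[group_a].sum() == 0 or lib[group_b].sum() == 0:
        raise ValueError("a group has all-zero libraries")
    factors = size_factors(matrix)
    norm = matrix.counts.div(factors, axis=1)
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    sum_a = matrix.counts[group_a].sum(axis=1).to_numpy()
    sum_b = matrix.counts[group_b].sum(axis=1).to_numpy()
    lib_a = float(lib[group_a].sum())
    lib_b = float(lib[group_b].sum())
    p_null = lib_b / (lib_a + lib_b)
    p_values = np.ones(len(matrix.counts))
    for i, (a, b) in enumerate(zip(sum_a, sum_b)):
        n = int(a + b)
        if n > 0:
            p_values[i] = stats.binomtest(int(b), n, p_null).pvalue
    fdr = multipletests(p_values, method="fdr_bh")[1]

    results = pd.DataFrame({
        "plate_id": matrix.counts.index,
        "mean_a": mean_a.to_numpy(),
        "mean_b": mean_b.to_numpy(),
        "log2fc": log2fc.to_numpy(),
        "p_value": p_values,
        "fdr": fdr,
    })
    results["significant"] = _significant_mask(results)
    return results


def _significant_mask(results: pd.DataFrame, fc_hi: float = 2.0,
                      fc_lo: float = 0.5, alpha_p: float = 0.05,
                      alpha_fdr: float = 0.05) -> pd.Series:
    fold = np.exp2(results["log2fc"])
    return (((fold > fc_hi) | (fold < fc_lo))
            & (results["p_value"] < alpha_p)
            & (results["fdr"] < alpha_fdr))


def call_significant(results: pd.DataFrame, fc_hi: float = 2.0,
                     fc_lo: float = 0.5, alpha_p: float = 0.05,
                     alpha_fdr: float = 0.05) -> pd.DataFrame:
    """Rows passing the joint fold-change / p / FDR cut-offs.

    Defaults are the study criteria: fold change > 2 or < 0.5 (fold > 2
    is the same condition as log2FC > 1), p < 0.05, FDR < 0.05.
    """
    mask = _significant_mask(results, fc_hi, fc_lo, alpha_p, alpha_fdr)
    out = results[mask].copy()
    out["significant"] = True
    return out.sort_values("fdr", kind="stable").reset_index(drop=True)


def write_results(results: pd.DataFrame, path) -> None:
    results.sort_values("fdr", kind="stable").to_csv(path, sep="\t",
                                                     index=False)
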