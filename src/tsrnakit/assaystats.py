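"""Validation-layer statistics: relative qPCR quantification and group
comparisons.

``ddct_fold_change`` implements the 2^-ddCt method: expression of a target
gene relative to a reference gene, in a treated sample relative to a
control sample. ``group_compare`` dispatches to a two-sample two-tailed t
test for two groups and a one-way ANOVA for more, the conventional choices
for assay readouts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DdCtResult:
    gene: str
    delta_ct_treated: float
    delta_ct_control: float
    ddct: float
    fold_change: float


def ddct_fold_change(ct_target_treated: float, ct_ref_treated: float,
                     ct_target_control: float, ct_ref_control: float,
                     gene: str = "target") -> DdCtResult:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control;
    fold change = 2^-ddCt. A negative ddCt (target amplifying earlier in
    the treated sample) means up-regulation.
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control,
           ct_ref_control)
    if not all(math.isfinite(c) and c > 0 for c in cts):
        raise ValueError(f"all Ct values must be finite and > 0, got {cts}")
    d_treated = ct_target_treated - ct_ref_treated
    d_control = ct_target_control - ct_ref_control
    ddct = d_treated - d_control
    return DdCtResult(gene, d_treated, d_control, ddct, 2.0 ** (-ddct))


def group_compare(groups: Sequence[Sequence[float]],
                  equal_var: bool = True) -> dict:
    """Two-group t test or one-way ANOVA, as appropriate.

    Two groups: two-sample two-tailed t test (Student by default; set
    ``equal_var=False`` for Welch). More: one-way ANOVA. Degenerate input
    (all groups constant with equal means) is reported as p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    groups = [list(map(float, g)) for g in groups]
    variances = [stats.tvar(g) if len(set(g)) > 1 else 0.0 for g in groups]
    means = [sum(g) / len(g) for g in groups]
    if all(v == 0.0 for v in variances) and len(set(means)) == 1:
        logger.warning("all groups constant and equal; p = 1 by convention")
        method = "t-test" if len(groups) == 2 else "anova"
        return {"statistic": 0.0, "p_value": 1.0, "method": method}
    if len(groups) == 2:
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        method = "t-test" if equal_var else "welch-t-test"
    else:
        stat, p = stats.f_oneway(*groups)
        method = "anova"
    return {"statistic": float(stat), "p_value": float(p), "method": method}
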