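"""Relative qPCR quantification and group comparison utilities.

2^-ddCt converts Ct differences (target vs reference gene, treated vs
control sample) into a fold change; group_compare picks a t test or ANOVA.
"""

from tsrnakit import ddct_fold_change, group_compare

res = ddct_fold_change(ct_target_treated=20.0, ct_ref_treated=15.0,
                       ct_target_control=24.0, ct_ref_control=15.0,
                       gene="RARG")
print(f"{res.gene}: ddCt = {res.ddct:+.1f} cycles -> "
      f"fold change {res.fold_change:.1f} (treated over control)")

control = [1.00, 1.05, 0.95]
knockdown = [0.42, 0.39, 0.47]
cmp = group_compare([control, knockdown])
print(f"two-group comparison: {cmp['method']}, "
      f"t = {cmp['statistic']:.2f}, p = {cmp['p_value']:.2e}")
# A fold change of 16 means the target amplifies four cycles earlier
# relative to its reference in the treated condition.
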