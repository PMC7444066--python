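"""Scan a 3'-UTR for a tsRNA binding site, then break the site.

Plants the perfect reverse complement of a tsRNA inside a random UTR,
scans for sites, mutates four seed-paired positions (the reporter-assay
style wild-type/mutant comparison) and rescans.
"""

import numpy as np

import tsrnakit as tk
from tsrnakit.targets import ScanParams

tsrna = "TGGTGTCCTTGGAAAAAGGTTTTCA"
rng = np.random.default_rng(0)
pad = "".join(rng.choice(list("ACGT"), size=400))
utr = pad[:150] + tk.revcomp(tsrna) + pad[150:]

[site] = tk.scan_utr(tsrna, utr, "utr-wt")
print(f"WT site at {site.site_interval}, score {site.score:.0f} "
      f"(perfect complement scores {tk.perfect_score(tsrna):.0f}), "
      f"stability proxy {site.stability_proxy:.0f}, "
      f"seed matched: {site.seed_matched}")

mutant = tk.mutate_site(utr, tsrna, site, n_mut=4, seed=1)
mut_sites = tk.scan_utr(tsrna, mutant, "utr-mut", ScanParams(threshold=10.0))
print(f"after 4 seed mutations the best score drops to "
      f"{mut_sites[0].score:.0f}; at the default threshold (80) the "
      f"mutant still scores {'above' if mut_sites[0].score >= 80 else 'below'} it")
print(f"default-threshold sites on the mutant: "
      f"{len(tk.scan_utr(tsrna, mutant, 'utr-mut'))}")
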