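# Methods

This note documents the models and procedures tsrnakit implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the design choices made where the design was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Biological background

Transfer RNA loci give rise to discrete small RNAs, not random degradation
products. Cleavage within the anticodon loop (attributed to angiogenin)
splits the mature tRNA into 5′ and 3′ halves (~30–50 nt); cleavage near
the D-loop or T-loop releases the shorter tRF-5 and tRF-3 species
(~17–23 nt) anchored at the mature termini; wholly internal fragments are
i-tRFs; and the 3′ trailer of the primary transcript — released by RNase Z
cleavage and ending at the pol III oligo-T terminator — yields tRF-1.
Profiling studies of differentiating cells report bimodal fragment-length
distributions (17–23 and 30–36 nt), all six classes detectable, and
fragment 5′/3′ positions tracking the parental tRNA's landmarks.

## The extended reference

Each gene contributes one mapping target:

```
[ spliced mature body | CCA | first 50 genomic nt 3' of the gene ]
```

* Intron removal is exact interval excision (canonical tRNA introns sit
  immediately 3′ of mature position 37); no splice-site sequence checks.
* CCA is appended **unconditionally**, even when the gene happens to end in
  a genomically encoded CCA — no deduplication. Toy genes that already end
  in CCA therefore carry `...CCACCA` in the extended sequence; this is a
  documented convention, not a bug.
* Minus-strand genes are reverse-complemented at build time; all
  downstream coordinates are on the mature sense.
* Coordinates are 0-based half-open throughout. Landmarks (D-loop,
  anticodon loop, anticodon, T-loop) live in mature coordinates and never
  extend into the CCA or trailer; `trailer_start = mature length + 3`.

## Read processing

* **Adapter trimming** removes the read suffix matching an adapter prefix
  with overlap ≥ 6 nt, or truncates at the first internal full-adapter
  occurrence. There is no quality trimming; quality issues are reduced to
  rejecting reads with > 10 % N at assignment time.
* **Length filter**: inclusive 12–50 nt window by default. A narrower
  24–33 nt window is sometimes used in half-focused analyses and is
  available via parameters; note that on a 76-nt body 3′ halves run
  37–51 nt, so the default window truncates the longest of them (length-51
  fragments are dropped) — an inherent property of the window, preserved
  deliberately.
* **Hierarchical assignment**: each read is tested against miRNA, then
  rRNA, then the extended tRNA references; the search stops at the first
  category with any ungapped placement at ≤ `max_mismatch` (default 1)
  mismatches. Within the tRNA category the best hit minimizes mismatches,
  ties broken by lexicographic reference id then smallest start. A read is
  counted once at its single best placement; fractional multi-mapping
  counting was rejected for reproducibility. The aligner is an exhaustive
  deterministic scan (exact-substring fast path, then a vectorized
  sliding-window mismatch count), chosen over a heuristic mapper so that a
  brute-force oracle can certify it at test scale.

## Fragment classification

With `M = trailer_start`, anticodon loop `[s, e)` widened to
`W = [s − loop_tol, e + loop_tol)`, and terminal slack `end_tol`:

1. `start ≥ M − end_tol` → tRF-1
2. `start ≤ end_tol` and `end ∈ W` → 5′-half
3. `start ≤ end_tol` and `end < min W` → tRF-5
4. `end ≥ M − end_tol` and `start ∈ W` → 3′-half
5. `end ≥ M − end_tol` and `start ≥ max W + 1` → tRF-3
6. `start > end_tol` and `end < M − end_tol` → i-tRF
7. otherwise → unclassified

Defaults: `end_tol = 1`, `loop_tol = 3`. The loop tolerance is required
because documented halves cleave in the anticodon *stem* as well as the
loop: on a canonical 76-nt body the well-known 39-nt 3′ half starts at
position 40, one position past the annotated loop end plus one — inside
the widened window. Rule order matters: a 3′-anchored fragment that also
extends into the trailer keeps its 3′ class (its 5′ cut decides half vs
tRF-3), while fragments anchored at neither terminus that straddle the
CCA/trailer boundary match no class and stay unclassified, as does the
full-length mature tRNA. tRF-1 is defined by its start at the trailer
only; the oligo-T 3′ terminator is not enforced.

## License plates

`tRF-<length>-<code>` identifiers are reversible and alignment-free: the
sequence is split into 5-mer chunks (final chunk 1–4 nt allowed); chunks
of 1–2 nt map to one token character, 3–5 nt to two, over a 32-character
alphabet that excludes A/C/G/T. The decimal length field fixes the chunk
structure, so decoding is exact and distinct sequences get distinct
plates.

The token table is this package's own deterministic construction (base-4
chunk value written in base 32), with one published-registry compatibility
layer: the eight chunk→token assignments that are observable from the
public registry record of the tRF-39 half of tRNA-Thr-TGT
(`tRF-39-ZLBS5EOB3ZY61DE2`) are pinned into the table by transposition,
keeping each per-length table bijective. The registry's full lookup table
is distributed as a flat file rather than a formula and is not vendored
here; plates therefore agree with the registry exactly on pinned chunks
and are internally consistent everywhere. Code that needs
registry-faithful plates for arbitrary sequences should swap in the
registry's table; the module structure (a per-length dict pair) makes that
a one-line substitution.

## Profiling

Fractions (length histograms, class frequencies, tsRNA share) are computed
over configurable denominators; the library denominator `totals` is the
post-filter read total per sample, of which the tsRNA column sum is a
part. "TPM" follows the small-RNA convention: counts per million total
mapped small-RNA reads, with **no** transcript-length normalization —
discrete fragments are counted, not length-weighted. Positional coverage
records read-start and read-end depth per base of the extended reference
(end depth at the last covered base).

## Differential expression

The calling criteria are the standard joint cut-offs: fold change > 2 or
< 0.5 (equivalently |log2FC| > 1), p < 0.05, and Benjamini–Hochberg
FDR < 0.05. Under the hood:

* **Normalization**: median-of-ratios size factors over rows positive in
  every sample, rescaled to geometric mean 1; falls back to column totals
  when no such row exists.
* **Fold change**: `log2((mean_B + 1) / (mean_A + 1))` on normalized
  counts. The pseudocount keeps fragments undetectable in one condition
  (a real and interesting case: fragments absent at day 0 that peak at
  day 7) finite without special-casing.
* **Test**: a two-sided exact conditional binomial test. Pool each row's
  raw counts within groups; conditional on the row total `a + b`, the
  group-B count is Binomial(a + b, p₀) under the null, with p₀ = group B's
  share of the summed library sizes. Empirical-Bayes negative-binomial
  machinery was deliberately not re-implemented: the exact conditional
  test is deterministic, assumption-light and oracle-checkable, and the
  scientific content here is the cut-off-based calling.

**Assumptions and limitations.** Conditioning Poisson counts on their sum
gives a binomial, so the test is exactly calibrated under Poisson-level
variation (the suite verifies the type-I rate on Poisson nulls). It does
**not** absorb extra biological overdispersion across replicates: with
negative-binomial dispersion α (variance μ + αμ²) appreciably above ~0.02
at these depths, the pooled test becomes anti-conservative and the joint
cut-offs start admitting false positives. Accordingly the count simulator
defaults to α = 0.02 — mild, technical-replicate-scale overdispersion
under which the planted-effect contracts (exact recovery of six planted
tsRNAs at fold 4, zero false discoveries) hold — and α is a parameter, so
the breakdown regime can be reproduced deliberately. For strongly
overdispersed real data a replicate-aware NB test (e.g. DESeq2/edgeR)
should replace this one; the module boundary (`de_test` in, result frame
out) is designed to make that swap local.

## Target-site scanning

Sites are found by affine-gap local (Smith–Waterman/Gotoh) alignment of
the small RNA 5′→3′ against the reverse complement of the UTR, where
aligned identity = Watson–Crick pair and the patterns G/A and T/C are G:U
wobbles. Scores: WC +5, wobble +1, mismatch −3, gap open −8, gap extend
−2; positions 2–8 of the small RNA (1-based; the seed) are weighted ×2.
Sites with score ≥ 80 (default) are reported non-overlapping, best first
(found iteratively, masking each reported site's UTR columns). The
stability proxy −(3·GC + 2·AT + 1·GU) is a pairing-strength tally, not a
nearest-neighbor free energy; thermodynamic folding is out of scope.
Scanning is restricted to supplied 3′-UTRs by design (reporter-assay
convention); nothing prevents passing CDS or 5′-UTR sequence. The seed
mutagenesis helper rewrites WC-paired seed columns to the base that is
neither complement nor wobble partner of the small-RNA base — the maximal
per-column score loss — mirroring how reporter mutants are designed.

## qPCR and assay statistics

2^−ΔΔCt: ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control,
fold change = 2^−ΔΔCt; invariant under any constant shift of all four Ct
values, and fold change 1 ⇔ ΔΔCt 0. Group comparisons use a two-sample
two-tailed Student t test for two groups (Welch optional) and one-way
ANOVA for more; all-constant equal groups return p = 1 by convention. No
post-hoc tests, efficiency corrections or normality checks.

## The synthetic data: what it emulates, and what it does not

The read generator draws, per read: a category (tsRNA vs miRNA/rRNA
contaminant, with the tsRNA share scaled per day to rise from day 0 to a
day-7 peak — defaults 0.5/1.0/0.9/0.7 for days 0/7/14/21), then a fragment
class from a configurable mixture (defaults 0.20/0.20/0.20/0.15/0.15/0.10
for tRF-5/tRF-3/i-tRF/tRF-1/5′-half/3′-half), then cut positions
consistent with that class, with lengths in the 17–23 nt mode for short
classes and 30–36 nt for 5′ halves (3′ halves run 37–51 nt, forced by the
geometry of a 76-nt body). Reads are exact substrings of the extended
reference with the 3′ adapter appended; a TSV truth table records every
read's sample, parent, class and interval. Fixed seed ⇒ byte-identical
outputs. The count simulator plants a chosen number of rows at a true
fold change between two day groups (optionally "absent-then-peak": day-0
mean zero), all other rows identical across groups, counts
negative-binomial as above.

Deliberately **not** modelled: sequencing errors and quality-score
realism (quality strings are constant 'I'), PCR duplicates, chemical
modifications and the misincorporations they cause, mitochondrial tRNAs
as a separate category, piRNA filtering, paired-end mechanics (small-RNA
inserts are single-end post-trimming), and per-row abundance variation in
the count simulator's null rows. Passing tests therefore certify the
pipeline's logic — coordinate arithmetic, precedence, classification,
calibration under the stated sampling models — not robustness to
real-library artefacts.

Replicates default to 3 per timepoint (donor-lot-scale replication; a
stand-in, as sequencing-replicate structure is rarely reported). Problem
sizes in the suite (panels of 4–6 genes, 1.5–10 k reads per sample,
300–500-row count matrices, 20-seed recovery sweeps) were chosen as the
smallest at which the binomial-error bounds in the tests are meaningful.

## Numerical conventions

* DNA alphabet everywhere; U mapped to T on input; uppercase enforced.
* All intervals 0-based half-open; inclusive length-filter bounds.
* Ties in alignment are broken deterministically (lexicographic reference
  id, then smallest start; in the DP, match/extension preference is
  fixed), so every pipeline output is reproducible bit-for-bit for a
  given seed.
* Degenerate inputs: empty samples yield empty histograms/fraction maps
  with a logged warning rather than an error; zero library totals are
  errors where a denominator is required.
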