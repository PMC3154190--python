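# Methods

`speccount` implements the classic two-condition, label-free,
spectral-counting comparison used in shotgun proteomics: proteins are
quantified by the number of tandem mass spectra matched to their peptides,
compared between two biological conditions (generically A and B; by default
labelled `67NR` and `4T1` after the non-metastatic/metastatic mouse mammary
tumour lines this workflow is typically applied to), and the resulting
protein sets are tested for category over-representation. This note records
the model, the conventions, and the design decisions, in the order the
pipeline runs.

## Protein assembly and parsimony

The input is a table of peptide-spectrum matches (PSMs): each identified
spectrum carries a peptide sequence, the set of database proteins containing
that peptide, a condition label, and per-protein decoy flags. Assembly
proceeds in five steps.

1. **Evidence graph.** PSMs aggregate into a bipartite peptide→protein map;
   a peptide's spectral count in a condition is the number of PSMs with that
   peptide and condition. Distinct peptides are distinct amino-acid
   sequences — charge states and modifications are not distinguished.
2. **Indistinguishable proteins.** Proteins whose distinct-peptide sets are
   identical cannot be separated by the data and are merged into one group,
   reported under the lexicographically smallest accession.
3. **Parsimony.** The minimal set of groups explaining every peptide is a
   set-cover problem. The peptide-protein graph decomposes into connected
   components, which in real data are small (most proteins carry private
   peptides). Components with ≤ 16 candidate groups — in practice nearly
   all — are solved by exhaustive enumeration, so the reported list is
   provably minimal there; among equally small covers, ties go to the
   larger summed spectral count, then to lexicographically smaller
   representatives. Larger components fall back to greedy selection (most
   uncovered peptides first, same tie-breaks) with lazy re-evaluation on a
   max-heap. Pure greedy set cover is *not* always minimal — small sparse
   counterexamples exist where greedy picks one group too many — which is
   why the exact component solver is the primary path. Groups whose
   peptides are fully covered by the selected set (subset proteins,
   degraded fragments) are discarded. A peptide shared between two selected
   groups credits its counts to **both** (no splitting); total spectra are
   therefore conserved exactly only when no peptide is shared between
   selected groups.
4. **Evidence filter.** Only groups with ≥ 2 distinct peptides
   (`min_distinct_peptides`, default 2) are reported; one-hit identifications
   are discarded.
5. **Target-decoy FDR.** With a search database containing reversed copies
   of every protein (`REV_` prefix), the protein-level false discovery rate
   is estimated by the doubling rule FDR% = 100 · 2D/T, where D is the
   number of decoy groups among T total — a decoy hit implies an equally
   likely false target hit. A group is a decoy only if *all* its members
   are decoys; mixed groups count as targets. The reported FDR is rounded
   half-up to two decimals; the comparison against the configured maximum
   (default 5%) uses full precision. Decoy groups are then removed.

## Differential abundance

Decoy-free groups are partitioned by presence: `exclusive_A` (no condition-B
spectra), `exclusive_B`, or `shared`. For shared proteins the effect size is

    log2FC = log2(count_B / count_A)

with no pseudocount — zero-count proteins are exclusives by construction and
bypass fold-change analysis entirely.

Significance cutoffs are the mean ± 1 sample standard deviation (n−1
denominator) of the shared log2FC distribution, computed over **all** shared
proteins *before* any abundance filtering. A protein is `increased` when its
log2FC is strictly above the upper cutoff, `decreased` strictly below the
lower; values on a cutoff are `unchanged`. Because both cutoffs shift with
the mean, the classification is invariant to a global multiplicative
loading imbalance between conditions.

Loading is checked by the coefficient of variance of the two per-condition
spectral totals (sample SD over the two totals, divided by their mean); a
CV on the order of 1% indicates fold changes are not driven by loading.

Before over-representation analysis, shared proteins are restricted to an
inclusive total-spectra window (default 25–300): low totals give unstable
ratios, and very abundant proteins empirically sit inside the unchanged
band anyway. Exclusive proteins are retained regardless of total.
Immunoglobulins and hemoglobins (case-insensitive substring match on the
protein description; patterns configurable) are excluded from all groups —
they dominate blood-adjacent samples without being informative. The four
analytical groups handed to enrichment are then: (1) exclusive to A,
(2) shared + decreased + in-window, (3) shared + increased + in-window,
(4) exclusive to B. The groups are disjoint by construction.

Reported values are rounded half-up: cutoffs to 3 decimals, CV and FDR to 2.
Stored values keep full precision so that the exact identities
`upper − mean = mean − lower = SD` hold; rounding happens only at the
reporting boundary.

## Over-representation

For a sample of n identifiers drawn from a universe of N containing a
category of K members, observing k category members is scored by:

* **ratio of enrichment** R = k / (n·K/N), observed over expected-at-random
  (algebraically identical to (k/n)/(K/N));
* exact hypergeometric upper tail P(X ≥ k), computed by pmf summation
  (scipy's survival function — no normal approximation);
* Benjamini–Hochberg step-up adjustment across all categories tested
  (statsmodels), reported in input order.

A category is significant when adjusted p < 0.05 (strict) **and** k ≥ 2
(inclusive); output is ordered by descending ratio, the convention for
plotting the most enriched categories first. The universe is the set of
identifiers in the annotation file (the annotated-gene space standing in
for "the genome"); `universe_size` can be set larger to model unannotated
background. Sample identifiers absent from the universe are dropped with a
logged count, not errors. Note that BH adjusted p-values are not a numeric
fixed point of re-adjustment (re-applying the formula re-multiplies by
m/rank); what is invariant is the decision: thresholding adjusted values at
any α reproduces the step-up rejection set of the raw p-values.

## Synthetic data generator

The generator emulates the statistical structure of a pooled two-condition
spectral-counting experiment so every stage is testable with known ground
truth. Per-protein, per-condition expected spectra are LogNormal(μ=3.0,
σ=1.0) (natural-log parameters; median ≈ 20 per condition), giving realized
totals from the floor of 2 up to the low thousands at experiment sizes of a
few thousand proteins. Counts are Poisson draws around the expectations:
spectral counts are event counts, and the descriptive targets (totals
spanning ~2–1400, unit-scale log2FC dispersion) pin a family, not a
likelihood.

Shared-protein structure: a fraction `frac_differential` (default 0.10) of
shared proteins carries a planted effect of ±`effect_size_log2` (default
2.5, alternating sign); the rest get biological scatter
Normal(0.128, 0.25). The decomposition is deliberate: at this abundance the
mean Poisson log2-ratio noise contributes ≈ 0.35 variance, so the null SD is
≈ 0.64 and the realized mixture SD ≈ 1.0. Under mean ± 1 SD cutoffs this
predicts ≈ 88% specificity on nulls and ≈ 95% sensitivity on planted
effects, which the end-to-end tests assert (≥ 85% / ≥ 90%).

Condition totals are balanced to a target CV of 1.26 × 10⁻² by scaling the
condition-B expectations. Because totals are dominated by abundant
proteins, a nonzero unweighted mean log2FC can coexist with near-equal
totals only if effects anticorrelate with abundance; the generator plants
this tilt (slope chosen in closed form from the log-normal
weighted-vs-unweighted gap σ²/ln 2), so the most abundant proteins sit at
or below the mean fold change. Small-count clamping attenuates the realized
unweighted mean below the nominal 0.128 (to roughly +0.05…+0.10 at a few
thousand proteins); the mean stays positive and the SD unit-scale, which is
what the generator is specified to emulate.

Consistency guarantees: shared proteins are clamped to ≥ 1 spectrum per
condition; every observed protein receives at least two distinct observed
peptides, placed preferentially on peptides private to it; exclusive
classes are assigned only to proteins whose peptides are fully private
(a protein sharing a peptide would inherit cross-condition spectra);
decoy contaminants are private two-peptide groups. Ground truth is
validated against the emitted PSM table on every emission. One seed drives
every random stream (proteome, counts, annotation use distinct substreams
of the same seed), so every emitted file is reproducible from the
configuration alone.

What the generator does **not** emulate: peptide detectability and length
biases, saturation of spectral counting for very abundant proteins, shared
peptides between decoys and targets, replicate-level variance (duplicate
injections are pooled, as in the workflow it mirrors), or real GO/KEGG
topology (categories are random draws, optionally weighted toward a target
set). Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and decision rules under a realistic count model — not
robustness to every artefact of real LC-MS/MS data.

## Numerical and degenerate-input choices

* Sample SD (n−1) everywhere, including the 2-point loading CV.
* Half-up decimal rounding for reported values (Python's `round` is
  banker's rounding and is not used for reporting).
* FDR of an empty identification list is 0 with a warning.
* Fold-change cutoffs require ≥ 2 shared proteins; a record with zero
  counts in both conditions is rejected as impossible post-identification.
* An analytical group none of whose members appear in the annotation
  universe skips enrichment with a logged warning.
* Ties everywhere are broken by total order (spectral count, then
  lexicographic accession), so all outputs are invariant under input
  permutation; pipeline reruns with the same configuration are
  byte-identical.

## Problem sizes used in the validation suite

The test suite and the acceptance script regenerate all inputs
programmatically: worked examples run at the published scale (2825 groups);
parsimony is cross-checked against exhaustive minimal covers on 1000 random
instances of ≤ 12 proteins and ≤ 20 peptides; the hypergeometric tail is
verified against exact rational enumeration for all universes N ≤ 25 with
n ≤ 6; null calibration of the enrichment test uses 2100 uniform draws
(the discrete test's attainable level just below 0.05 — about 0.047 for the
category sizes used — is the quantity checked, within ±1.5 points); and
end-to-end recovery runs the full pipeline at the generator's 200-protein
default. These sizes make the whole suite run in well under a minute while
keeping every check exhaustive or statistically well-powered at its scale.
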