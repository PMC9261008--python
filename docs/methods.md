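# Methods

`ftdprot` implements a stratified label-free proteomics analysis for
case/control brain-tissue cohorts measured by data-independent acquisition
(DIA) with gel fractionation, of the kind used to contrast genetic
frontotemporal dementia (FTD) subtypes against non-demented controls
(NDC). This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic data do and do not
demonstrate.

## Quantification model

The raw observable is a peak area per (peptide, sample, gel fraction)
with an identification quality value `q` from spectral matching.

**Presence filter.** A (peptide, fraction) stratum is kept when the share
of samples with `q <= 1e-3` reaches 50%, evaluated either over all
samples (`global` mode, used for a cohort-wide overview) or within at
least one of the two compared conditions (`pairwise` mode, used for each
disease comparison — it keeps proteins that are expressed in only one
condition). The 50% threshold is inclusive: a peptide identified in
exactly half of one condition's samples survives. Measurements failing
the cut inside a retained stratum are set to missing rather than deleted,
which makes the filter idempotent and keeps the rule auditable after the
fact. Absent measurements count as failing when shares are computed.

**Cyclic loess normalization.** Between-sample intensity-dependent bias
is removed on the log2 peptide-fraction matrix with the fast cyclic
variant: at each of 3 iterations every sample column is adjusted against
the row-mean reference by subtracting a robust degree-1 loess fit of
M = sample − reference on A = (sample + reference)/2 (span 0.7, three
bisquare reweightings, fitted values interpolated across near-duplicate
abscissae at 1% of the A-range for speed). Missing entries are ignored in
fitting and remain missing. Normalization precedes fraction summation; a
config switch (`normalize_before_rollup: false`) moves it after, for
sensitivity analyses.

A caveat worth stating plainly: loess normalization assumes most features
are unchanged between groups. When a large minority of proteins carries
strong planted effects (the default synthetic conditions plant ~15% at
4-fold), the fitted trend absorbs part of the group difference and
redistributes small systematic shifts onto null features. Those shifts
are real features of the normalized matrix, so the permutation test
flags some of them: the end-to-end pipeline's empirical FDR at `q < 0.05`
runs above its nominal level (~0.2 under the default conditions), while
the test itself is well calibrated on matrices that reach it without
normalization. This is a property of normalize-then-test designs, not of
the implementation; the manifest reports the measured FDR so it is never
hidden.

**Rollup.** Peptide abundance is the linear-scale sum of its top two
fractions; protein abundance is the sum of its top five peptides. "Top"
is decided once per feature by the mean linear abundance across samples —
not per sample, which would confound abundance with missingness — with
ties broken by feature identifier for determinism. Inside a selected
top-k set, missing entries contribute zero; a feature whose selected
members are all missing in a sample stays missing there. Peptides mapping
to multiple proteins are an error by default (`drop` and `assign-all`
policies are available; protein-group inference is out of scope).

**Reproducibility summary.** The technical-replicate coefficient of
variation is SD/mean of linear protein abundances within each replicate
group, averaged over groups per protein, summarized by the median over
proteins. For log-normal noise with natural-log SD s the closed form is
sqrt(exp(s^2) − 1), which the tests use as an oracle.

## Differential expression (SAM)

Per protein, on log2 abundances with pairwise-complete group statistics:

    d_i = (mean2_i − mean1_i) / (s_i + s0)

with `s_i` the pooled-SD two-sample standard error. The fudge factor `s0`
follows the Tusher search: among percentiles 0, 5, …, 100 of the `s_i`,
choose the value minimizing the coefficient of variation of the median
absolute deviation of `d` across 20 s-quantile windows. `--s0 fixed:<v>`
bypasses the search.

Significance uses balanced group-label permutations — exhaustive when the
number of distinct assignments fits the budget (e.g. all C(6,3) = 20 for
a 3v3 design), otherwise 1000 seeded draws without replacement, always
including the observed labelling, with `s0` held fixed. The p-value pools
permuted `d` across proteins. The q-value at threshold t = |d_i| is
pi0 × median over permutations of the null exceedance count, divided by
the observed exceedance count, clipped to [0, 1]; following the q-value
convention each protein then takes the minimum over all thresholds at or
below its own |d|, making q monotone non-increasing in |d|. pi0 is the
IQR estimator (share of observed d inside the pooled null interquartile
range, divided by 0.5, capped at 1). Proteins with fewer than two
observations in a group are reported untested (NaN), not q = 1.

Fold changes are ratios of linear group means (condition2/condition1) by
default; exponentiated mean log2 differences are available via
`fc_method="log-means"`. Discovery is two-sided at `q < 0.05`, and the
significant set is partitioned into higher (fold > 1) and lower (fold
< 1) expressed proteins for downstream interpretation.

Under 200 global-null simulations (100 proteins, 8 vs 8, 1000
permutations) the mean fraction of q < 0.05 calls is below 0.01 and
pooled p-values pass a KS uniformity test; at the planted-recovery
benchmark (40 up + 40 down at 4-fold, n = 10/group, log2 noise SD 0.3)
sensitivity exceeds 0.9 at observed FDR below 0.1.

## Cell type enrichment

**Specificity.** From a labelled cell × gene single-cell reference
(clustering and labelling are inputs, not performed here; cells labelled
`unknown` are excluded), expression is library-size normalized per cell
and averaged within each type; a gene's specificity for a type is that
type's share of the summed type means, so rows sum to 1.

**EWCE bootstrap.** A protein list's enrichment per cell type compares
the summed specificity of the list to 20,000 same-size uniform draws
without replacement from the quantified background. p = (#{boot ≥ obs}
+ 1)/(n_boot + 1) — never exactly zero; floor results are flagged
`at_floor` ("< 1/n_boot"). Fold enrichment is observed over bootstrap
mean and z is in bootstrap SDs; p is BH-adjusted across cell types.
Random lists are length-matched but not expression-level matched (a
level-matched mode is not provided in this release; the bootstrap draws
are uniform). When the null is small enough to enumerate the `exact`
mode replaces sampling by full enumeration.

**Highly-enriched classification.** A protein is assigned the cell type
for which its specificity reaches 0.5 — unique by construction above 0.5.
With `merge_neurons`, excitatory and inhibitory columns are summed into
one neuron column first (post-merge ties go to the larger specificity).

**Composition-change diagnostic.** Because whole-tissue fold changes can
reflect cell-ratio shifts rather than regulation, control-vs-control
variation defines a reference band: controls are repeatedly split into
balanced halves (exhaustively when feasible, else 100 seeded splits), the
per-protein log2 ratio of half-means is computed, and its SD is pooled
across proteins and splits. For each highly-enriched protein set the
report gives the fraction of disease/control log2 fold changes inside
±2 SD and the fraction of significant proteins outside. Regulation
concentrated in one cell type shows up as that set leaving the band at a
far higher rate than the others, which a mere change in cell numbers
would not produce for the unaffected types.

## Overrepresentation

Hypergeometric upper-tail enrichment of a protein list against gene-set
terms, with membership intersected with the quantified background first
and terms below five background members skipped. Multiple testing uses
Benjamini-Hochberg within each ontology namespace; the web-server
correction tied to a specific term ensemble is deliberately replaced by
BH, and the result metadata records this. For presentation, the
best-per-parent rule keeps a significant term iff, under at least one of
its parents in the DAG, it has the smallest p among that parent's
significant children (ties: larger overlap, then term id); significant
roots are always kept. A generic subtree partition assigns list members
to ontology roots (e.g. pre-/postsynaptic) by reachability, with
multi-assignment allowed.

## Cross-cohort comparison

Two cohorts are compared strictly on their jointly quantified proteins:
shared significant proteins (q < 0.05 in both), cohort-distinct ones,
direction concordance among shared hits (fold changes on the same side
of 1), and paired SAM effect sizes with the share of proteins stronger
in one cohort (ties count half). Unrestricted DE counts are reported
alongside for transparency. Nominal-only proteins (p < 0.05 but
q ≥ 0.05) count as not significant.

## Synthetic data

The generator emulates, on log2 scale: protein baselines (N(20, 2)),
peptide and fraction offsets, planted group effects (default 15% of
proteins at log2 fold change 2, optionally tied to cell-type marker
sets), per-sample scale biases (SD 0.25), and i.i.d. measurement noise.
Technical replicates share every effect except noise. Identification
quality values are a two-point mixture (pass 1e-4 / fail 1e-2) whose
pass probability rises logistically with the noise-free latent abundance
(midpoint 16, scale 1.5), so missingness is abundance-dependent and
acts through the filter rather than through absent rows. `noise_sd`
defaults to 0.35, calibrated so the protein-level replicate CoV after
rollup is ~0.13, the one distributional anchor available for this kind
of experiment; cohort sizes default to 10 per group, within the 8-13
range typical of post-mortem brain cohorts. Default problem sizes (300
proteins, 1-8 peptides each, 4 fractions; 5,000-20,000 bootstrap lists;
1000 permutations) keep a full run in seconds while leaving every rule
(top-k selection, minimum term size, exhaustive-vs-sampled permutation)
exercised on both sides of its threshold.

The single-cell generator draws negative-binomial counts (gamma-Poisson,
dispersion 0.5) with disjoint marker sets per type enriched by a known
factor, giving the closed-form specificity e/(e + n_types − 1) for
markers. The ontology generator grows a rooted DAG in which every
child's gene set is a subset of its parents' union.

What passing tests show — and do not. The simulations validate the
algebra and the statistical calibration of each stage and the
end-to-end plumbing. They do not emulate correlated peptide noise,
interference, shared-peptide ambiguity, batch structure, or the ~40%
mRNA-protein correlation that limits transcriptome-derived specificity;
conclusions about real tissue still require the usual orthogonal
validation.

## Known limitations

- Normalization leak under dense strong effects, described above.
- The control-band SD pools over proteins, so proteins with atypical
  variance are judged against an average band.
- Gene/protein identifier harmonization is exact uppercase symbol match;
  no alias tables.
- Paired or covariate-adjusted designs, protein-group inference and
  ranked (GSEA-style) enrichment are out of scope.
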