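# Methods

`newsecm` implements the desk-side analysis of a chemoselective newsECM
(newly synthesized extracellular matrix) enrichment experiment: tumor
tissues are metabolically labeled with an azido sugar (Ac4GalNAz), labeled
glycoproteins are captured on streptavidin after desthiobiotin conjugation,
and label-free LC-MS/MS quantifies the protein fractions before ("input")
and after ("eluate") the pull-down.  This note records the models, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Normalization, prefilter, outliers

Total-intensity normalization scales protein `X` in sample `i` of group `K`
by `Sum_average / Sum_Ki`, where `Sum_Ki` is the sample's total intensity
and `Sum_average` the *arithmetic* mean of the totals over the group (the
geometric mean is a plausible alternative; the arithmetic mean is what the
"average sum" formulation implies and what the conservation property
assumes).  Three groupings cover the use cases: one group per
(model, treatment) arm, one group over all selected samples, one group over
all input samples.  Totals are always computed over all rows of the table
being normalized; species subsetting (e.g. a human-only analysis) must be
applied *before* normalizing, mirroring the human-prefiltered workflow.
Normalization is exactly conserving (all post-totals in a group equal the
pre-normalization group mean), idempotent, and invariant (up to one global
factor) to rescaling any single sample.

The detection prefilter splits proteins into a *testable* set, with at
least `k = 2` nonzero values in **both** comparison groups, and a
*qualitative* set that cannot receive a numerical p value and is reported
via group means instead of being dropped.

Grubbs's test is the classical two-sided single-outlier test:
`G = max|x - mean| / sd` against `((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2))`
with `t = t_{1-alpha/(2n), n-2}`, at `alpha = 0.05`.  One pass flags at
most one value (ties break to the lower index); iteration is available but
off by default, since the source workflow does not state whether the test
was iterated.  The enrichment-QC runner applies it to per-sample
protein-group counts and totals within a treatment arm, not to individual
protein intensities.

## Missing values and QRILC imputation

Input tables encode non-detection as 0 (the MetaMorpheus LFQ convention);
zeros become missing only at the log2 stage.  Dropout in such data is
missing-not-at-random and left-censored: low-abundance proteins fall below
the detection limit.  QRILC (quantile regression imputation of
left-censored data) exploits this: per sample, if a fraction `pi` of values
is missing, the observed empirical quantile at level `u` corresponds to the
complete-distribution quantile at `pi + u(1-pi)`; regressing observed
quantiles (fit range `u` in (0.001, 0.5), 100 points) on the matching
standard-normal quantiles yields `(mu, sigma)` of the complete
distribution.  Missing cells are then drawn from `N(mu, sigma^2)` truncated
**above** at `mu + sigma*(Phi^{-1}(pi) - tune)`, with `tune = 0.001` as a
small safety margin; imputed values therefore never exceed the estimated
censoring point.  A sample needs at least 20 observed values for a stable
fit.  On censored-Gaussian simulations (N(20, 2^2), 15% censoring, 5000
proteins) the fit recovers `(mu, sigma)` within 5%.

## Differential statistics

Welch's two-tailed t-test with Satterthwaite degrees of freedom is
implemented vectorized (needed for permutations) and verified against an
independent implementation to 1e-12.  Degenerate conventions: zero variance
in both groups with equal means gives `t = 0, p = 1`; a constant nonzero
difference gives `|t| = inf, p = 0`.

Permutation FDR follows the Perseus-style recipe: group labels are
reassigned — exhaustively when the number of distinct assignments is at
most 10,000 (126 for the 4-vs-5 cross-model layout), else a seeded random
subset, always including the observed assignment — and the pooled null
|t| distribution gives, per protein, `FDR = (mean permutation count of
null |t| >= |t_obs|) / (observed count of |t| >= |t_obs|)`.  q values are
the step-down minimum of FDR over all proteins at least as insignificant,
enforced monotone along increasing *p* (not |t|: the two orderings differ
slightly because df varies per protein), clipped to [0, 1].  For a single
protein with exhaustive permutations q reduces exactly to the permutation
p value.  The s0 fudge term is 0 (plain Welch t): only the plain test is
described for the source workflow, and the exact Perseus session settings
(balanced vs unbalanced permutations, s0) are unrecorded, so the estimator
is validated by its FDR-control property on null simulations rather than by
bit-compatibility with any published q values.

Fold changes are ratios of geometric means; `log2 FC` equals the difference
of mean log2 intensities, so imputed log2 values can be exponentiated
first with no effect (the documented equivalence).  Volcano classes:
high-in-A iff `log2FC > 1` and `q < 0.05`; high-in-B iff `log2FC < -1` and
`q < 0.05`; boundary values (`log2FC = ±1`, `q = 0.05`) are
non-significant.  The plotted p cut-off line sits at the largest p among
proteins with `q < 0.05`.  Sample correlations are pairwise-complete
Pearson r (>= 3 shared observed proteins, otherwise flagged), with p from
the t-transform of r.

Whether imputation is applied is a per-comparison switch (`PipelineConfig.impute`):
the cross-model comparison uses QRILC, while labeled-vs-vehicle
comparisons can run on observed values only, as described for the source
workflow.

## Matrisome and species accounting

Matrisome annotation maps accessions to division (core matrisome /
matrisome-associated / non-matrisome) and category (collagens, ECM
glycoproteins, proteoglycans, ECM regulators, ECM-affiliated, secreted
factors); unmatched accessions default to non-matrisome.  A protein counts
as *identified* in a fraction when nonzero in at least one of its samples
(`min_nonzero`, default 1 — no replicate threshold is stated for the
published counts).  Intensity proportions are per-sample category shares
averaged over the fraction's samples; the eluate/input ratio of those
shares is the composition-shift readout.

Species recovery is `100 x (species eluate sum) / (species input sum)`,
with sums taken as per-sample means so unequal replicate numbers cancel,
on tables of comparable intensity scale (raw, or jointly normalized).  A
proportion-relative definition (ratio of species *shares*) was considered
and rejected: shares sum to one in both fractions, so two species cannot
simultaneously have recoveries of 87.5% and 30% on that definition — the
reported numbers are only consistent with absolute intensity ratios.
Contaminant share is the intensity percentage of proteins whose gene symbol
matches curated actin/tubulin/histone prefixes (ACT[ABCG]*, TUB[ABDEG]*,
HIST*/H1-/H2A/H2B/H3/H4); the list is overridable since only the families,
not a matching rule, are specified.

## The synthetic proteome generator

The generator is the test bed: it emits tables with the exact statistical
structure the pipeline assumes, plus ground truth.

**Abundance model.**  Per-protein log2 intensity is
`meanlog + m_i + d_ik + eps_ij`: a shared protein effect `m_i`, a
model-level effect `d_ik` (only in two-model configurations), and replicate
noise `eps`.  Defaults `meanlog = 20`, total sd `abundance_sdlog = 2` (log2
units, ~4 orders of magnitude across proteins, typical for LFQ).  The
variance split is derived from the targeted replicate correlations:
`var(m) = rho_b * V`, `var(d) = (rho_w - rho_b) * V`,
`var(eps) = (1 - rho_w) * V`, where `rho_w`, `rho_b` are *latent* pair
correlations chosen so the **observed** (post-censoring,
pairwise-complete) correlations hit the configured within-model R² (0.94)
and between-model R² (0.49).  Left-censoring truncates the abundance
distribution and attenuates Pearson r, so the generator numerically inverts
the attenuation: the observed correlation of a soft-censored bivariate
normal is computed on a standardized grid and the latent correlation found
by root bisection.  Without this correction the emitted data would
systematically undershoot the configured R².

**Enrichment mechanisms.**  Labeled vs vehicle eluates differ through two
independently tunable mechanisms, because detection fold and intensity fold
are separate observables: (1) only a uniformly chosen subset of
`round(n / detection_enrichment)` proteins is present in vehicle eluates
(background binding); (2) the vehicle arm is intensity-scaled so the truth
(pre-censoring) total-intensity ratio equals `intensity_enrichment`
exactly.  Both are calibrated exactly on truth means — censoring removes
the same per-sample quantile from both arms, so the folds survive
censoring unbiased.

**Composition calibration.**  Species shares, contaminant share, and
matrisome category proportions are measured on *observed* (post-censoring)
intensities, and censoring bites hardest exactly where these blocks live
(low-abundance rat, contaminant, secreted-factor proteins).  The generator
therefore calibrates these block scalings against the *expected observed*
intensity, computed deterministically by Gauss-Hermite quadrature over the
replicate noise with the censoring rule applied, iterated to a fixed point.
Truth-level enrichment folds stay exact; composition statistics become
unbiased as measured.

**Censoring model.**  Each sample censors around its own
`censor_quantile = 0.15` intensity quantile with a soft sigmoidal boundary
(`P(missing) = expit((q - v)/softness)`, `softness = 0.3` log2 units), so
dropout probability is monotone non-increasing in abundance — the
left-censoring structure QRILC assumes.  No mechanism for the real data's
dropout is documented; this is the minimal model consistent with QRILC.

**Study presets.**  The dECM-tumor preset (5 labeled / 3 vehicle eluates,
5 inputs) uses detection fold 5.3, intensity fold 23.4, human recovery
0.875, rat recovery 0.30, contaminant input share 0.36%, and category
proportion ratios {collagens 0.26, regulators 2.0, proteoglycans 2.9,
secreted factors 9.2}.  The rat share of *input* intensity is not reported
anywhere; 3.42% is the unique value consistent with the two recoveries and
the 1.2% residual rat eluate share, and is fixed in the preset.  The
tumoroid preset (5/5, human-only) uses folds 9.0 and 11.0 and contaminant
share 0.81%.  The cross-model preset (4 + 5 labeled eluates, human-only)
carries the correlation structure; multi-model configurations are
restricted to human-only proteomes, matching the human-database search used
for cross-model comparisons.  The category composition of the input
(collagen-dominated, with numerous low-abundance secreted factors) and the
per-category protein counts are design choices, not reported values; the
replicate noise scale is likewise a free parameter derived from the R²
targets rather than a published variance.

**What the generator does not emulate:** peptide/spectrum-level structure,
retention time, match-between-runs artifacts, batch effects, interference
between co-eluting species, or biologically structured (pathway-level)
covariance beyond the shared protein/model effects.  Passing benchmarks
therefore show the *pipeline* is correct under the assumed statistical
model, not that the model captures every property of real LC-MS/MS data.

## Synthetic images and the DAPI map

Synthetic fields are 256x256 RGB: a tissue region formed by 3 random disk
blobs (radius 40-65 px), ~350 nuclei (radius 3-6 px, intensity 0.9) placed
only inside the tissue, signal channels with configured in/out-of-tissue
means (defaults 0.8/0.1 red, 0.5/0.1 green) plus Gaussian noise (sd 0.02),
clipped to [0, 1].  With no nuclei there is no tissue and the truth mask is
empty.

The DAPI map pipeline: percentile contrast stretch (1st-99th, the
"saturation balance" step — no specific method is published, so this is a
parameterized choice), binarize at threshold 0.15, remove 8-connected
components below 50 px, then morphological closing (dilate + erode) with a
disk of radius 25 px to connect nuclei into a tissue approximation.  The
threshold, size cutoff and disk radius used in the original MATLAB program
are unpublished; these defaults are declared, exposed in the config, and
recorded in output provenance, not claimed to match.  At these defaults the
map reaches Dice >= 0.9 against the generator's truth across 20 seeded
fields (nucleus spacing is well below twice the disk radius, the condition
for closing to fill the interior).  Region statistics are arithmetic means
inside/outside the mask; the pixel-count-weighted combination of the two
reconstructs the global channel mean to 1e-9.  Empty regions and zero
references are flagged (NaN) rather than raised.

## Problem sizes and determinism

The standard benchmark size is 2000 proteins per dataset with at most
10,000 permutations per comparison (exhaustive 126 for 4 vs 5), 20 synthetic
images at 256x256, and 50-seed null batteries for FDR control; one full
benchmark run takes seconds on a single core.  Every stochastic stage takes
an explicit seed (`numpy.random.default_rng`); identical configuration and
seed reproduce byte-identical tables and reports, and written CSVs carry a
config-hash + seed header.

## Known limitations

* q values are validated by FDR control and exactness properties, not by
  bit-compatibility with Perseus (whose session parameters are unrecorded).
* The generator's composition profile and noise scale are calibrated study
  conditions, not measured ones; absolute intensities are arbitrary units.
* Species assignment of ambiguous protein groups follows the first-listed
  accession; shared-peptide effects are not modeled.
* The image model uses disk-shaped tissue and uniform stain levels; it does
  not emulate uneven illumination, autofluorescence gradients, or z-stack
  artifacts.
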