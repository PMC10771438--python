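# Methods

## The screening model

The pipeline assumes each cell line `l` in a panel of `n` lines has a
scalar differentiation propensity, observed two ways:

- **Marker panels** (per differentiation protocol): relative expression
  of `m` NS/PC marker genes, quantified as 2^-ddCt against a reference
  transcript, in `r` biological replicates per line. Replicates are
  averaged arithmetically (matching how such panels are usually plotted
  and summarized), each marker is standardized to mean 0, SD 1
  (denominator n−1), and the propensity index is the projection of the
  standardized rows onto the leading eigenvector of the m×m marker
  correlation matrix (PC1). Correlation-matrix PCA, not covariance PCA,
  because the inputs are explicitly z-scored; explained variance is the
  leading eigenvalue over the eigenvalue total. The PC1 sign is not
  identified by the eigendecomposition, so it is oriented so the loadings
  sum positive (tie broken toward a non-negative first loading): higher
  PC1 then means uniformly higher marker expression by construction.
  Lines are ranked in descending PC1; exact score ties are broken by
  lexicographic line id and flagged.

- **Expression screen**: for every probe that survives the across-line
  filter, per-line replicate-mean expression is rank-correlated with the
  PC1 ranking. For untied data r_s = 1 − 6Σd²/(n³−n) with integer Σd²,
  which makes the statistic exact; significance is judged against the
  exact permutation null (below). Because r_s is invariant to any monotone
  transform, correlating against PC1 ranks or PC1 scores is identical on
  untied data (asserted in the tests).

## The exact permutation null

Under no association, all n! pairings of two untied rank vectors are
equally likely, and r_s is a deterministic function of Σd², so the null
is the distribution of Σd² over permutations. The package tallies it
with a dynamic programme over value subsets (state = set of ranks already
assigned × running Σd²), which is exact and fast (n = 10 in ~20 ms);
direct enumeration of all n! permutations serves as the independent test
oracle for n ≤ 6. Properties used as test invariants: counts sum to n!,
Σd² is always even (Σd² ≡ Σd mod 2 = 0), the distribution is symmetric
about 0, the mean is 0 and the variance exactly 1/(n−1).

Two-sided P-values are inclusive tails P(|R| ≥ |r| − ε) with a snapping
tolerance ε = 1e-9, so floating-point representations of achievable
support values are counted inclusively. The critical value at level α is
the smallest achievable non-negative support value whose two-sided tail
probability is ≤ α; at n = 10 and α = 0.01 this is Σd² = 34, i.e.
r = 1 − 204/990 = 0.7939…, printing as 0.794 with achieved α = 0.00878. Consequently
significance is inclusive at the printed threshold (a gene at exactly
0.794 is called), which also matches how published candidate tables
include boundary values. When no support value qualifies (e.g. n = 3 at
α = 0.01, minimum two-sided P = 2/6), the critical value is reported as
unattainable with that explanation rather than silently clamped.

Enumeration is capped at n = 10 (3,628,800 permutations — the design
point of the study size); beyond that a seeded Monte-Carlo null over
random permutations is provided and flagged approximate. Ties cannot
occur for continuous intensities; if they do occur (discrete input), the
midrank product-moment r_s with a t approximation (df = n−2) is used and
the call carries a prominent `tied` flag, because the permutation null is
only exact for untied data.

## Probe filtering

The upstream "line-variable probe" selection is under-specified in the
source material, so the filter is the one across-line test the workflow
names: one-way ANOVA of log2 expression across lines, Benjamini–Hochberg
adjusted at 0.05 by default, fully configurable (`adjust="none"`, an
optional mean-expression floor). Zero-variance probes have undefined F
and are dropped with a logged warning, never raised. Reproducing the
study's exact kept-probe count is not attempted — the original criteria
are not stated — but the default probe total (3,362) matches the size of
the filtered set the screen operated on.

## The synthetic generator

`simulate_panel` draws one latent propensity per line from Uniform(0,1)
(continuous, so ranks are almost surely untied — the regime the exact
null assumes) and derives everything from it:

- **Marker panels.** Per-line marker means are base_m · F^u, where u is
  the min–max-scaled latent propensity and F the protocol's fold range
  (defaults 5 for suspension, 15 for adhesion, the dynamic ranges the
  two protocols show). With zero noise the max/min marker-mean ratio
  therefore equals F exactly (tested at 1%). Replicates get
  multiplicative log2-normal noise.
- **Planted genes.** A planted gene's line ordering is a permutation of
  the latent ordering at the nearest achievable even Σd² to
  (1−ρ)(n³−n)/6, realized by randomized local search over transpositions;
  per-line means are then an affine monotone map of that ordering
  (amplitude 2.0 log2 units across the panel), negated for "−" genes.
  This makes `planted_rho` a *constructive* dial — the planted rank
  correlation equals the nearest achievable value to ρ (exactly ±1 at
  ρ = 1, 0.903 at ρ = 0.9 for n = 10) — rather than the expectation of a
  noisy bivariate draw, whose sample r_s at n = 10 would be too variable
  to make planted-marker recovery a meaningful test at fixed ρ.
- **Background probes.** Half of the non-planted probes (configurable)
  carry line-specific offsets N(0, 0.4) independent of propensity — the
  probes the ANOVA filter should keep and the screen should reject — and
  the rest are flat, which the filter should drop. Replicate noise is
  N(0, 0.2) on the log2 scale (~15% CV, typical replicate-level
  variability for array and qPCR data).

`simulate_kd_timecourse` plants a ±log2fc mean shift (alternating signs)
in `n_de_genes` genes at every day of a control/knockdown design, with a
shared per-day drift so days differ but contrasts within a day are clean.

**What the generator does not emulate.** Both protocols' panels are
driven by the *same* latent propensity and differ only by replicate
noise, so their PC1 rankings are nearly identical — more concordant than
real protocol pairs, whose orderings genuinely disagree for some lines.
Two consequences: (i) protocol-exclusive planted correlations cannot be
generated (a gene correlated with the shared latent shows up in both
screens), so the sign-concordance and exclusivity logic of the
intersection is tested on hand-constructed orderings instead; (ii) the
cross-protocol intersection filters background false positives less than
it would on real data, because a chance correlate of one protocol's
ranking is almost surely a correlate of the other's. Passing tests
therefore demonstrate recovery and calibration of each stage and of the
planted signal end to end, not the real-data false-positive yield of the
intersection. Probes are also independent given the line, with no
correlation structure, batch effects, or array-level normalization
artifacts.

## Calibration checks

Three end-to-end properties anchor the test suite, all computed over 100
seeded panels at the default study conditions:

- the shared negative planted marker lands in the cross-protocol negative
  intersection in ≥ 90 runs;
- under a full global null (no planted genes, no line effects) the
  intersection is non-empty in ≤ 5 runs — this bound is inherited from
  the BH-adjusted ANOVA filter, which under a global null admits any
  probe with probability ≤ 0.05; the screens alone could not deliver it,
  since the two protocols' near-identical rankings make their false
  positives coincide;
- the knockdown stage recovers planted 4-fold effects (3 replicates,
  noise 0.1) with ≥ 95% power, and under the null its realized
  false-discovery proportion averages ≤ 0.05.

## Numerical and design choices

- 2^-ddCt with the calibrator group's **mean** dCt as baseline, so the
  calibrator's geometric-mean relative expression is exactly 1; samples
  missing a Ct are excluded with a warning record, not an error.
- The knockdown contrast uses a plain two-tailed unpaired t-test per
  gene; vendor array pipelines use moderated statistics, so absolute
  gene counts from such software are not comparable and are not targets.
  FC > |2| is interpreted as |log2FC| > 1.
- No multiple-testing correction across probes in the screen itself: the
  design relies on the exact small-sample threshold plus cross-protocol
  replication, mirroring the workflow it implements (an optional BH mode
  exists on the filter only).
- Reported correlations round to 3 decimals (round-half-even); all
  comparisons happen on unrounded values with the 1e-9 snap.
- Explained variance is scale-free (eigenvalue ratios of the correlation
  matrix), so the n vs n−1 convention in standardization cancels.

## Problem sizes

Default simulations are 10 lines × 6 expression replicates × 3,362
probes, with 100-seed batteries for the calibration checks; these sizes
keep the full suite under a minute on one CPU while exercising the exact
n = 10 null the method is built around.
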