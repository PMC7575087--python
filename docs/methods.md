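# Methods

This note documents the models, defaults and design choices behind
`ohnodiverge`, and what the synthetic-data tests do and do not establish
about real data.

## Ohnologue calling

A gene tree is accepted as evidence for an Ss4R ohnologue pair when the
two focal-species (Atlantic salmon) genes sit in a clade that is
monophyletic for salmonid species, has Northern pike as its sister
group, and is mirrored in at least one other salmonid; the pair must
additionally be supported by an Ss4R collinear block (one gene in each
of the block's two intervals, either orientation). Choices where the
criteria admit readings:

* **Sister group** (`sister_mode`): the default `exact` requires the
  sister subtree's species set to equal {pike}; `contains` relaxes to
  pike being present. Exactness is the stricter reading and is what the
  synthetic negatives exercise; mixed sisters typically indicate
  incomplete lineage sorting or tree error, which a caller should not
  silently accept.
* **Conservation in another salmonid** (`conservation_mode`): default
  `mirrored` requires some non-focal salmonid to contribute a leaf to
  *each* duplicate sub-clade (the two children of the clade node) — the
  signature of the duplication predating the salmonid radiation.
  `any2` relaxes to two leaves anywhere.
* **Ambiguity**: clades with more than two focal genes (tandem
  duplicates inside the Ss4R clade) are reported as ambiguous, never
  resolved by guesswork.
* **Rooting**: unrooted newick input is rejected. The sister-group
  criterion depends on the root, so rooting must be an explicit
  upstream decision.
* **Rediploidization classes**: mean windowed percent identity m maps
  to late (m > 95), mid (90 ≤ m ≤ 95), early (m < 90). The boundaries
  are configurable; the published description gives colour bands and an
  approximate early value (~87 %) rather than exact cut-points, so the
  class edges at 90 and 95 are this package's convention.
* Coordinates are 1-based inclusive; strand is ignored (position is the
  only locus information the criteria use). Leaf labels follow
  `gene|species|chr:start-end`; because a bare colon reads as a newick
  branch length, labels are quoted on write and auto-quoted on parse.

## Normalization

cpm is computed on effective library sizes (library size × TMM factor).
TMM uses the published defaults — 30 % two-sided trim on M (log
ratio), 5 % on A (log abundance), precision weighting, reference sample
chosen by the upper-quartile rule, factors rescaled to geometric mean
1 — and matches edgeR's `calcNormFactors` to ≤ 1e-6 on test fixtures.
The expression filter keeps genes with ≥ 1 cpm in ≥ 5 libraries and is
idempotent. When log2 output is requested, a +0.5 count offset is
applied before division and recorded in the matrix provenance.

## Rhythm detection

The detector is a rank test of JTK-cycle's family: cosine reference
waveforms with fixed 24-h period are laid on a phase grid matching the
4-h sampling resolution (6 candidate peak phases), each template is
reduced to ranks at the sampled times (replicates entering as tied
observations), and the statistic is the maximum Kendall tau-b over the
grid. The p-value is the permutation tail probability *of that
maximum*, so the phase search is corrected by construction. Amplitude
and mesor come from a least-squares cosinor at the winning phase, on
log2 expression; a negative fitted amplitude folds the phase by 12 h.

**Permutation scheme.** By default all observation labels are permuted
freely (`scheme="observations"`), which is exactly valid when residuals
are independent across samples — true of the generator and the designs
tested here. A block scheme that permutes timepoints as replicate
blocks is available (`scheme="blocks"`) for designs with shared
within-timepoint effects; with only 7 timepoints it is markedly
conservative (a permuted 7-level sinusoid often still matches some
phase template), and the free scheme was made the default for that
reason. Default n_perm is 5000 (1000 in the bundled large screens);
p-values are (1 + #{null ≥ observed}) / (n_perm + 1), so the smallest
attainable p is 1/(n_perm + 1). Requests below 100 permutations are
refused. Constant series get tau = NaN and p = 1.

Analysis windows follow the sampling designs: diel uses ZT5 through the
following ZT5 (both endpoints retained, giving tied clock-times at 5 h),
constant light/dark use CT9–CT29. Period scanning is not attempted; the
period is fixed at 24 h, matching the diel/circadian question. BH
adjustment is applied within each tissue × condition stratum.

## Differential expression

A single common NB dispersion is estimated by maximizing the
sum-constrained (conditional) likelihood over all genes, on counts
scaled to the geometric-mean effective library size, over a log-spaced
grid refined by bounded scalar optimization; the Poisson boundary
(dispersion 0) is an admissible answer. Tagwise shrinkage is
deliberately omitted — the target gene sets are small and no shrinkage
settings are part of the published description — and this is a known
limitation for genes whose dispersion departs far from the common one.

The FW/SW **exact test** conditions on the sum of the two group totals:
group sums of iid NB counts with common mean are NB with summed shape,
so the conditional law of one group's total is computed directly from
the two group-sum pmfs (binomial in the Poisson limit). Unequal
libraries are handled by scaling counts to a common effective size
before conditioning — analytic conditioning in place of
quantile-adjusted pseudo-counts; the two agree at these depths, and the
analytic route is testable against exhaustive enumeration. Two-sided p
sums all outcomes no more probable than the observed one. log2FC is
computed from mean cpm with a +0.5 offset.

The **time-course test** fits an NB log-linear model (log effective
library size as offset) with a stage factor against intercept-only at
the common dispersion; the deviance difference is referred to
chi-square with (stages − 1) degrees of freedom. GLM fitting uses
statsmodels IRLS; an independent Fisher-scoring implementation in the
test suite agrees to 1e-6 in deviance.

FDR is controlled by Benjamini–Hochberg within each contrast, threshold
0.01.

## Divergence measures

* **EDI** = |log2(expr1/expr2)| on tissue-mean normalized expression.
  When either value is exactly 0, a 0.5-cpm offset is added to *both*
  values, keeping the index finite, symmetric and zero for identical
  inputs. EDI is invariant to common positive scaling.
* **Profile divergence**: each series is divided by its own mean over
  the compared window ("normalized to group mean" on the ratio scale),
  then fit by a sixth-order polynomial in (t − t̄). The polynomial is
  linear in its coefficients, so the shared-vs-separate comparison is an
  exact nested-OLS F test: F = ((RSS_sh − RSS_sep)/k) / (RSS_sep/df),
  k = 7 coefficients, df = N₁ + N₂ − 2k. Significance threshold 0.01.
  At 7 distinct timepoints the order-6 fit interpolates the timepoint
  means; the test then compares within-timepoint scatter against the
  gap between the two genes' mean curves.
* **Seawater interaction**: two-way ANOVA on log2(cpm + 0.5) with
  factors gene-copy and condition; the interaction term is the
  extra-sum-of-squares comparison of the additive against the full
  model, well-defined also for unbalanced cells. Default alpha 0.05;
  the published account uses both 0.05 and 0.01 in different places, so
  both thresholds are surfaced in the pipeline config rather than
  resolved.
* **Clustering**: profiles standardized per gene, distance
  1 − Pearson r, average linkage, tree cut at k = 5 (k configurable; 5
  mirrors the five observed developmental archetypes and no automatic
  k selection is attempted). Input rows are sorted by gene id first, so
  the result is order-independent; zero-variance profiles are excluded
  with a warning.
* **Report**: per assay, a pair is `one-copy-regulated` when exactly
  one copy is significant and `different-dynamics` when both are but
  fall in different clusters (or the profile/interaction test rejects);
  a pair showing the two distinct modes across assays is `both`.
  Because the report consumes FDR-controlled calls, occasional
  pair-level false positives at the configured FDR are expected and are
  not a defect of the report logic.

## Synthetic-data generator

The generator emulates the study designs: a multi-tissue atlas (11
tissues × 3 replicates), the diel/LL/DD circadian design (4-h sampling,
diel ZT5–ZT29 at 7 timepoints, LL from CT9, DD from CT1, n = 3), the
six-stage smoltification course (n = 6) and the FW/SW challenge
(n = 6). Counts are NB(mean = library_size × 2^(baseline + cosine +
archetype + seawater term), dispersion), baseline ~ N(5, 1.5²) log2 cpm,
dispersion 0.05 by default, library sizes log-uniform within 2-fold of
10⁶ so normalization is actually exercised. The cosine convention is
signal = amplitude × cos(2π(t − phase)/24) with phase = peak time;
amplitudes are log-normal with median 2 log2 units; constant-condition
amplitudes are multiplied by a per-tissue damping factor (default 0.5).
Developmental archetypes are five standardized curves (rise, fall,
peak, trough, late induction) scaled to 1 log2 unit per sd; seawater
effects are N(2, 0.5²) log2FC on a responsive subset.

Planted effects are assigned **pair-coherently**: both copies of a true
pair share their rhythm/archetype/response unless the pair is drawn
divergent (probability `frac_divergent_pairs`, default 0.3), in which
case the second copy is silenced or moved to another archetype and the
pair is recorded in the ground truth. The recorded divergent set is
therefore exactly the set of regulatorily differing pairs, which is
what the report is validated against.

Negative orthogroups (probability `p_loss_post_wgd`) exemplify one
labelled defect each — lost duplicate, non-salmonid intruder in the
clade, wrong/mixed sister, missing mirrored pair, or loci outside any
collinear block — enabling per-criterion precision tests. Each negative
orthogroup contributes one genuine focal singleton; violation trees
additionally carry a decoy focal gene that is excluded from the
expression gene universe.

One pseudo-random stream per artifact (trees, synteny, expression) is
derived from the master seed at fixed offsets, so generating one
artifact never perturbs another, and identical configs give
byte-identical outputs.

**What the generator does not model** — and what passing tests
therefore do not establish about real data: mapping/quantification
error, GC or length bias, batch effects shared within timepoints
(replicates are iid; the block permutation scheme exists for the
contrary case), tagwise dispersion heterogeneity, correlated genes
(counts are independent across genes given the design), tissue-specific
amplitude differences beyond uniform damping, and partial (as opposed
to all-or-none) loss of rhythm in a diverged copy. Composition effects
*are* partially modelled: because the simulated matrix contains only
clock genes, planting many large effects strains total-count and TMM
normalization exactly as a small targeted panel would; the bundled
designs keep planted-effect mass moderate for that reason.

## Numerical choices

* Permutation p-values include the identity permutation in numerator
  and denominator (never 0); ties with the observed statistic count as
  exceedances at 1e-12 slack.
* The conditional NB likelihood is evaluated with log-gamma functions
  on continuous library-equalized pseudo-counts; the dispersion grid is
  geometric on [1e-4, 4] with 25 points before refinement.
* OLS fits use `numpy.linalg.lstsq`; the order-6 Vandermonde on
  centered hours (range ±12) is well within double-precision
  conditioning for these designs.
* Exact-test pmfs are normalized over the observed total's support to
  absorb truncation error; two-sided tails use a (1 + 1e-12) tolerance
  when comparing outcome probabilities.
* Degenerate inputs: all-zero genes give p = 1 (exact test) / LR = 0
  (time course); constant series give p = 1 in the rhythm test;
  zero-variance profiles are dropped from clustering; empty
  mesor groups return NaN rather than raising inside table builders.

## Problem sizes

The bundled tests and the acceptance script run at the study-design
scales: 200 orthogroups for the caller benchmark, 500 pairs × 11
tissues for EDI, 1000 genes × 1000 permutations for rhythm calibration,
1000 null pairs for the profile-F calibration, 2000 genes for
dispersion recovery, 120 orthogroups × 6 stages × 6 replicates for the
smoltification benchmark, and 200 replicate simulations for the
interaction-power estimate.
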