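# Methods

This note documents the statistical machinery in `micropair`, the choices
made where the design was genuinely open, and what the synthetic data can
and cannot tell you about real paired-platform studies.

## Compositional model

Sequencing counts carry only relative information, so every abundance
analysis runs on compositions.  The preparation chain, in order:

**Genome-length normalisation** (shotgun only).  A cell of a 6 Mb genome
contributes ~3× the shotgun reads of a 2 Mb genome at equal cell counts,
so counts are divided by genome length.  Each row is then rescaled back
to its original library size: downstream steps are compositional, so only
the proportions matter, and keeping read-like totals makes reports easier
to read.  Normalisation precedes filtering, so the prevalence filter sees
length-corrected proportions.

**Prevalence/abundance filter.**  A taxon is kept when its within-sample
relative abundance reaches `min_rel_abundance` (default 0.1%) in at least
`ceil(min_sample_fraction · n)` samples (default 5%).  The ceiling keeps
the "at least 5% of samples" guarantee exact for non-divisible `n`.  The
filter is monotone in both thresholds (relaxing either never removes a
kept taxon), which the tests exercise.

**Zero replacement.**  Bayesian-multiplicative imputation under a uniform
Dirichlet prior whose strength is the square root of the sample depth:
for a sample with depth `n` over `D` parts, each zero is imputed at
`p₀ = (√n/(n+√n))/D`.  Because `p₀` can exceed the sample's detection
limit when `D < √n`, it is additionally capped at 0.65× the smallest
observed proportion — an imputed part must stay below anything actually
seen.  Non-zero parts are shrunk by the common factor `1 − Z·p₀`
(Z = number of zeros), so every pairwise ratio among observed parts is
preserved exactly and rows stay closed.  The replacement returns
proportions; Chao1 and rarefaction deliberately run on the raw integer
counts instead.

**clr transform.**  `clr(x)_j = ln(x_j/g(x))`; rows sum to zero (checked
to 1e−9).  PCoA of the resulting Aitchison distances is algebraically the
PCA of the clr matrix, an identity the test suite asserts coordinate-wise
to 1e−8 — it is the strongest single check that the distance, the double
centering and the eigendecomposition are all consistent.

## Taxonomy harmonisation

Synonym maps are user-supplied per-rank tables, applied once; maps must
be idempotent (chains `A→B→C` are rejected at load).  Taxa whose
canonical lineages coincide after replacement are summed.  Roll-up to a
rank groups columns by that rank's name; taxa lacking the rank go to an
explicit `unassigned@rank` bucket that is flagged unnamed — overlap
statistics (which run on named taxa only) skip it, while compositions
stay closed.  Slash-ambiguous 16S species whose candidate sets intersect
are merged transitively (union–find over shared candidate binomials);
the merged taxon takes the alphabetically sorted candidate union and the
summed counts, which makes the operation idempotent and total-preserving.
Cross-platform species matching after harmonisation is by exact string
equality; any-candidate matching can be had by expanding the synonym map.
Accession-code-only taxa (configurable prefixes, default `MGYG`) are
excluded from overlap accounting but participate in everything
compositional.

## Concordance statistics

"Detected" means a non-zero **raw** count — detection is a property of
the sequencer output, so zero replacement plays no role there.  Cohen's
kappa uses the marginal-product expected agreement and is undefined
(reported as NaN, tallied separately) when both raters are constant on
one category.  Median binarization thresholds each taxon at its
across-sample median within a platform, ties mapping to 0; per-sample
kappa restricts those full-table binarizations to the sample's shared
taxa, and at species rank slash-ambiguous taxa are excluded from rho and
kappa by default.  The abundance comparison correlates the platforms'
compositional centres (per-taxon geometric means, closed to sum 1) over
shared taxa with Spearman's rho.

## Diversity

Shannon entropy is depth-sensitive, so every sample is rarefied
(multivariate-hypergeometric subsampling, one seeded draw; a
mean-over-draws mode exists) to its platform's minimum depth, computed
from the data rather than hard-coded.  Chao1 estimates unseen richness
from singletons and doubletons; the bias-corrected form is the default
because it is defined when `F₂ = 0`, with the classic form behind a flag.
Platform distributions are contrasted with the unpaired Wilcoxon
rank-sum test (the conventional presentation for platform contrasts; a
paired signed-rank option exists but is off by default), and paired
values are correlated with Spearman (headline) and Pearson (secondary).
Sparsity is the per-sample zero fraction; group contrasts use
Kruskal–Wallis with a Bonferroni guidance threshold of 0.05/12 when the
test is repeated across ranks, platforms and filtering states.

## Ordination comparison

ANOSIM (`R = (r̄_between − r̄_within)/(n(n−1)/4)` on distance ranks) and
PERMANOVA (pseudo-F from the between/within partition of squared
distances) are implemented in-package with vectorised label permutations:
every permutation stream takes an explicit seed, and the vectorisation
makes thousand-dataset calibration sweeps cheap.  scikit-bio's
implementations serve as independent oracles in the tests.  Permutation
p-values use the `(b+1)/(m+1)` convention (never zero); the default is
999 permutations.  Pairwise PERMANOVA post-hocs are Benjamini–Hochberg
adjusted.

Procrustes similarity uses the symmetric formulation on the ordinations'
positive-eigenvalue axes truncated to the smaller configuration's axis
count — no arbitrary two-axis cut-off — with `r = √(1−m²)` and a
row-permutation test.  The RV coefficient
`RV = tr(XᵀY YᵀX)/√(tr((XᵀX)²)·tr((YᵀY)²))` is computed on PCoA
projections by default (raw clr input is accepted).  The six datasets are
summarised by the spectral decomposition of their pairwise RV matrix,
`K = UΛ²Uᵀ` with plotted coordinates `UΛ`; K's diagonal is fixed at 1,
entries clipped to [0, 1], and small negative eigenvalues (> −1e−10)
clipped to zero while a substantially indefinite K is rejected.

## Machine-learning comparison

One stratified split (default 10 test samples per class, seeded) is
reused for both platforms and all ranks, so every cross-model comparison
runs over identical samples.  The SVM is an explicit one-vs-one ensemble
of three binary linear SVMs (control–HRL, control–CRC, HRL–CRC) combined
by majority vote; a cyclic tie is broken by the largest summed absolute
decision value, then by class order.  Hyperparameters come from 5-fold
stratified CV maximising mean accuracy — cost grid {0.1, 1, 10, 100} for
the SVM; trees {500, 1000, 2000} × minimum node size {2, 3} for the
random forest — with ties resolved toward the simpler model.  RF
importance is the impurity decrease (the conventional default;
permutation importance behind a flag); SVM importance is the mean
absolute hyperplane weight across the three binary models, with
per-binary rankings also retained.  Accuracy CIs are percentile
bootstraps over test indices (n = 2000); prediction-agreement kappa gets
an asymptotic CI; Kendall τ-b over shared-taxon importances gets a
bootstrap CI resampling taxa.  Signature sizes default to top-50 species,
top-20 genera, top-10 families.

## Synthetic data: what it emulates, and what it does not

Each sample draws a latent log-normal community (species means
N(0, 1.5²), per-sample spread N(0, 1²) — a standard null for microbiome
simulation).  Diagnosis effects shift `n_signature` species (default 10)
in log space by `effect_size` for CRC and half of it for HRL, encoding
the adenoma–carcinoma continuum.  Shotgun observes all species
multinomially with probabilities ∝ abundance × genome length (lengths
uniform on 1–8 Mb); 16S observes a `detect_frac_16s` subset (default
0.6) with probabilities ∝ abundance × rRNA copy number (1–12 copies),
perturbed by log-normal noise scaled by `1 − coupling` (default
coupling 0.8), then partially collapsed into within-genus slash groups
(default rate 0.2, matching the roughly one-in-five ambiguity seen in
SILVA-classified ASVs).  Extra 16S-only species (default 15%) appear
under lineages absent from the shotgun table, and 10% of shotgun species
carry accession-code names.  Default arm sizes are 51/54/51 — the
three-arm screening cohort layout — and default mean depths are 50,000
(shotgun) and 5,000 (16S) reads: scaled to keep a full run fast while
preserving the order-of-magnitude depth gap and hence the sparsity
ordering; study-scale depths are one config field away.

The generator does **not** emulate read-level artefacts (chimeras,
contamination, primer mismatch), strain structure, database-version
disagreements beyond simple name disjointness, or compositional
interactions between taxa.  Passing tests therefore demonstrate that the
statistics and their couplings behave correctly on data with this
structure — not that any particular real cohort will show the same effect
sizes.

A subtlety worth recording: under label shuffling, training both
platforms' models on the *same* permuted labels does **not** drive their
prediction kappa to zero — both models overfit the same label noise
through the coupled community, and kappa settles near 0.35.  The correct
null for "no shared diagnostic signal" permutes each platform's training
labels independently over a common test set; the test suite calibrates
kappa against that null.

## Numerical conventions

Closure and clr checks use 1e−9; eigen-identities 1e−8; rank-statistic
oracle comparisons 1e−10.  Ties in every ranking (top-prevalent taxa,
importance orderings) break alphabetically, making reports reproducible
byte-for-byte under a fixed seed.  All stochastic stages (rarefaction,
permutation tests, CV folds, RF, bootstraps, the split, the generator)
consume explicit seeds recorded in the run manifest.  Degenerate inputs
are errors, not silence: all-zero samples reject zero replacement,
non-Euclidean distance inputs reject PCoA, singleton groups reject
ANOSIM/PERMANOVA, and constant binarizations make kappa NaN with an
explicit undefined tally.

## Problem sizes used in validation

The test suite and acceptance script run the generator at 24–156 samples
with 60–240 species and depths of 2,000–50,000 reads; permutation-test
calibration uses 1000 null datasets of 30 samples with 199 permutations
each; ML null behaviour averages over 10–20 seeds.  These sizes were
chosen to make the distributional claims (type-I error within ±0.02 of
α, chance-level accuracy within ±5 points) statistically meaningful while
keeping a complete validation run in the minutes range.
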