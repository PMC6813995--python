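# Methods

This note documents the models, numerical choices and known limitations of
`osteorate`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Bone-section profiling

A section is a binary raster (foreground = mineralized tissue). The
reference area is the hole-filled mask; validity requires at least one
foreground pixel and exactly one non-negligible connected component after
hole-filling (components below 1% of the largest are treated as trabecular
specks, not fragments — porous cortices shed a few isolated pixels and real
sections do too). Grayscale inputs are binarized at 50% of their dynamic
range, which absorbs anti-aliased edges.

The radial coordinate is normalized **per angular sector** by that sector's
boundary distance from the section centroid, so elongated rib-like sections
map onto [0, 1] sensibly. The centroid is taken on the hole-filled mask —
cavity placement must not shift the reference frame. Defaults: 60 sectors ×
51 radial bins; per-bin compactness is the pooled foreground fraction, i.e.
sectors are weighted by pixel count.

The sigmoid `C(x) = Min + (Max−Min)/(1+exp((P−x)/S))` is fit by bounded
(trust-region) least squares with bins weighted by pixel count. Logistic
fits have well-known local optima, so five deterministic starts are used —
P ∈ {0.2, 0.4, 0.6, 0.8} with S = 0.1, plus a moment start at the
mid-compactness crossing; the best weighted RSS wins, ties broken by
smaller S. Bounds: S ∈ (1e-4, 1], P ∈ [0, 1], Min, Max ∈ [0, 1]. Profiles
with weighted variance below 1e-4 carry no transition; they return Min =
Max = mean with S and P missing rather than a spurious fit.

Center and periphery regions for Cc/Cp default to relative radius ≤ 1/3 and
≥ 2/3. This is a declared convention (symmetric thirds approximating
medulla and cortex), configurable per call — upstream tooling that
motivated these indices does not publish its delimitation. MD is the
maximal Feret diameter of the filled mask, which matches "maximal diameter"
for non-circular sections; it is multiplied by the pixel size when one is
given, otherwise reported in pixels.

## Trees and phylogenetic covariance

Trees are rooted, Newick-parsed via dendropy, with branch lengths required
on all non-root edges. Labels are whitespace-normalized to underscores;
matching against trait tables is exact after normalization, and species
missing from either side are pruned with the subtree re-rooted at the MRCA
of what remains (the root-to-tip statistic is always relative to the MRCA
of the retained species). Ultrametricity is checked at 1e-6 × depth and
recorded, not required — published calibrated trees are near-ultrametric.
Polytomies are accepted; nothing downstream needs binary trees.

`C(1)[i,j]` is the root-to-MRCA path length; Pagel's λ multiplies
off-diagonals only, so C(λ) = λC(1) + (1−λ)diag C(1). Brownian simulation
draws tip vectors through one Cholesky factor per (tree, λ), vectorized
over replicates.

## Root-to-tip dN/dS

The per-species statistic accumulates branch-wise dN and dS along the
root-to-tip path. Two constructions are exposed because the phrase "average
accumulated dN/dS" admits both: the default `path_ratio` (Σ dN / Σ dS),
which absorbs near-zero-dS branches into the sums, and
`mean_branch_omega`, which averages per-branch ω and is undefined whenever
a path branch has dS below 1e-6. Reports state the mode. The codeml
free-ratio parser rebuilds the branch/node graph from the `dN & dS for each
branch` table itself and maps tip numbers onto the taxon-name tree printed
in the same file, so branch identity is carried as child-clade tip sets —
portable to any congruent species tree.

## PGLS, λ estimation and the two-step procedure

The regression model is y ~ N(Xβ, σ²C(λ)). Fitting whitens by the Cholesky
factor of C(λ) and solves OLS in whitened coordinates. λ̂ maximizes the
profile log-likelihood (σ² profiled at RSS/n) by bounded scalar
minimization on [0, 1] (tolerance 1e-6) with both endpoints evaluated
explicitly — the optimum is frequently at a boundary. Coefficient P values
use t statistics with n − k degrees of freedom and the unbiased σ̂² =
RSS/(n−k); r² is 1 − RSS/TSS in the whitened space against the GLS
intercept-only fit (this is the definition closest to what comparative
packages report; alternatives exist, hence the documentation). Singular
designs raise an error naming the collinear columns; fewer than
max(4, k+1) complete cases is an error, and listwise deletion always prunes
the tree to the cases used.

The two-step procedure reports *P.all* from the full fit; *P.robust* after
deleting the single species with the largest absolute whitened residual;
and *P.max*, the maximum slope P over single-species deletions. *P.max*
defaults to deletions from the **full** sample — the stricter,
order-independent reading — with the alternative (deletions after the
robust-step removal) available via a flag. λ is re-estimated in every
refit.

Body-size correction fits PGLS of the bone variable on the size proxy (MD
or CL) and carries the **response-scale phylogenetic residuals** into the
rate regression as the new response, consistent with the PGLS framework
used throughout (ordinary residuals would reintroduce phylogenetic
structure the main fit then mis-models).

### Calibration, and a known limitation

The acceptance suite measures the slope test's type-I error at n = 27, λ=1
over 500 null replicates with a Brownian predictor: it sits inside
0.05 ± 0.02. Under the full study conditions the screen's null rejection
runs slightly above nominal (near 0.07 at α = 0.05) for two intrinsic
reasons: the plug-in of λ̂ is mildly anti-conservative at this sample size
when the predictor is itself strongly phylogenetically structured — as
root-to-tip rates are, since sister species share most of their path — and
the habitat clade shift makes the response not exactly Brownian, so even a
correctly specified λ cannot fully whiten the residuals. A matched control
(λ fixed at its generating value on habitat-shift-free null cohorts, where
the model is correctly specified) sits at the nominal 0.05, certifying the
GLS core; both numbers are computed by `scripts/acceptance.py`. REML
estimation of λ was tried and does not remove the plug-in effect. This
behaviour is shared by the standard plug-in PGLS methodology this package
implements and is one reason the two-step deletion P values exist; the
screen reports raw P values (with an optional Benjamini–Hochberg column),
and the acceptance checks hold the full-conditions false-positive rate to
within a factor of two of nominal while requiring the matched control to
sit in the tight 0.05 ± 0.02 band.

## Phylogenetic ANOVA

The observed statistic is the classical one-way F. The null distribution is
simulated: the Brownian rate σ² is ML-estimated from the observed trait on
the tree (single-mean GLS), n_sim traits are drawn (default 1000), and
p = (1 + #{F_sim ≥ F_obs}) / (n_sim + 1), so the smallest attainable P is
1/(n_sim+1). Pairwise post-hoc pooled-variance t statistics are referred
two-sided to the same simulated null and Holm-corrected, matching the
defaults of the R implementation this procedure is standard in. A constant
trait returns P = 1; groups with fewer than two members are an error. The
acceptance suite shows the simulated null holds the 0.05 level under
clade-clustered groups where ordinary ANOVA rejects more than half the
time.

## PCA

Vertebral indices mix counts, lengths and dimensionless ratios, so the
decomposition is of the correlation matrix (standardized variables) by
default, with the covariance alternative behind a flag. Scores are named
Vpc1, Vpc2, …; signs are fixed so each component's largest-magnitude
loading is positive; constant variables are an error naming the column.

## Selection LRTs

The LRT statistic 2(lnL_alt − lnL_null) is clamped at zero; a null
likelihood exceeding the alternative by more than 1e-3 log-units warns of
an upstream optimization failure. The branch-site test is referred to χ²₁
by default — the conservative choice, since the appropriate boundary
reference (a 50:50 mix of a point mass at zero and χ²₁) is available but it
is not documented which convention the upstream analyses used. CmC vs
M2a_ref uses df = 1 (one extra divergent-class ω). Multi-start stability
requires all three starts ω₀ ∈ {0.5, 1.0, 1.5} present and a log-likelihood
spread ≤ 1e-2 (configurable — "unchangeable" has no published number); the
best start is carried forward. PSG requires branch-site P < α; DSG requires
CmC P < α **and** stability; the foreground-specific divergent label
additionally requires ω₂ > 1 and ω₁ < 1. This module never runs a codon
optimizer.

## Synthetic cohorts

The generator's defaults are the study conditions: 27 tips, 348 candidate
genes, tree depth 1, σ² = 1, λ = 1, aquatic habitat offset 3 tip-standard
deviations on S and Cc (positive) and Cp (negative), size correlation 0.5
for S/Cc/Cp with the lognormal body-size proxy MD, ω baseline 0.2, dS rate
0.2 per unit branch with lognormal noise (sd 0.2). Trees are pure-birth
(Yule): exponential waiting times between speciations plus a final
Exponential(n) stretch to the present, so terminal branches are never
zero-length; depth is normalized to 1. Habitat is painted on the clade
closest to one third of the tips (or shuffled at random).

Coupled genes have branch ω = baseline + effect × (focal trait at the
branch midpoint), floored at 0.01; midpoint trait values come from the
simulated ancestral states directly — no reconstruction step. dN carries
its own multiplicative lognormal noise (sd 0.2): branch-wise rate estimates
from finite alignments are noisy, and without this term every uncoupled
gene would have a *constant* root-to-tip value and the null side of the
screen would be degenerate. The default effect size 0.05 was calibrated
once so that a coupled gene is flagged with roughly 90% power at n = 27,
α = 0.05.

With λ_true < 1 the tips receive an extra independent normal component so
tip covariance equals the λ-scaled Brownian matrix; branch-midpoint truth
values then follow the underlying Brownian process (exact only at λ = 1,
the default).

What the generator does **not** emulate: real codon-level sequence
evolution (dN/dS noise is lognormal, not estimation error from an
alignment), intraspecific variability and measurement error in bone
indices, missing data patterns, non-Brownian trait evolution
(Ornstein–Uhlenbeck pull, rate shifts), and correlated evolution among the
bone variables beyond the shared size factor and habitat offsets. Passing
tests therefore demonstrate internal statistical correctness and
calibration under the stated model, not robustness to every way real
comparative data violate it.

Bone-section images place foreground pixels inside a circular or elliptical
boundary with probability given by the sigmoid at the pixel's normalized
radius; this is the exact inverse of the profiling model, so parameter
recovery is a closed loop (the acceptance suite holds mean absolute error
of Ŝ and P̂ at or below 0.05 over 50 sections at 512²).

## Problem sizes used in checks

Acceptance computations use 500 replicates for the two type-I calibrations
(27 tips; ANOVA nulls of 399 simulations each), 100 replicates × 100 genes
for the screen, 50 sections at 512² for profile recovery, and ≤ 8-taxon
fixtures for the exact-oracle comparisons — sizes chosen so the whole suite
reruns in minutes on one CPU while keeping Monte-Carlo error well below the
tolerances tested.
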