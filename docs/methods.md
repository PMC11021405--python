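# Methods

This note documents the models, numerical choices and design decisions
behind `tradescape`, and what the synthetic studies used in testing do and
do not establish about real data.

## Shape geometry

Generalized Procrustes analysis centers each configuration, scales it to
unit centroid size, and iterates rotation-to-the-mean (Kabsch, reflections
disallowed by default) until the mean shape changes by less than 1e-10 in
Frobenius norm (at most 100 iterations). The aligned unit-size
configurations are then projected orthogonally onto the tangent plane at the
mean, x → x + (1 − ⟨x, m⟩)·m, the standard linearization for downstream
multivariate statistics; `mean_shape` is recomputed as the mean of the
projected coordinates so that the alignment invariants hold exactly.

The PCA of the flattened tangent coordinates uses an SVD; eigenvalues are the
per-component score variances (n−1 denominator), and each eigenvector is
flipped so its largest-magnitude loading is positive, making signs
platform-independent. Shape reconstruction is the linear map
mean + Σ scoreₖ·eigenvectorₖ, exact for specimens in the sample.

The theoretical grid extends the empirical PC1/PC2 range by a total of 10%
per axis, split 5% per end. The convention ("total, split equally" vs "per
end") is genuinely ambiguous in common usage; the symmetric-split total is
adopted and exposed as a parameter.

## Performance surfaces

Candidate families:

* **polynomial** — least squares on all bivariate monomials up to the total
  degree (1–5);
* **tps** — thin-plate spline with kernel r²·log r and polynomial drift;
  "order" d (2–4) means drift degree d−1. The smoothing penalty is chosen by
  generalized cross-validation: with P = Q₁R the drift design and
  B = Q₂ᵀKQ₂ = UDUᵀ the kernel reduced to the drift-orthogonal complement,
  RSS(λ) and the effective degrees of freedom n − Σ λ/(dᵢ+λ) are available in
  closed form, and GCV is minimized over a 40-point log-spaced λ grid scaled
  to the kernel spectrum (λ = 0 interpolates and can be requested
  explicitly);
* **kriging** — ordinary kriging; the empirical semivariogram is binned to
  half the maximum pairwise distance (12 bins), candidate variogram models
  (spherical, exponential, Gaussian) are fitted by weighted least squares
  with the automatic-variogram weights N_h/h², and the family with the
  lowest weighted SSE is kept. The kriging system carries a 1e-10 jitter so
  near-zero fitted nuggets stay solvable.

Model selection is by k-fold (default 10) cross-validated RMSE with a
seeded, shared fold partition; ties break toward fewer free parameters, and
candidates that cannot be fitted on some training fold are reported as
failed rather than dropped. Functional metrics are min–max scaled to [0, 1]
*before* fitting, over the theoretical-shape sample. Surface predictions are
never clipped: off-sample values may leave [0, 1], and the trade-off
machinery treats non-positive combined values as an error unless an explicit
floor (1e-9) is requested.

## Trade-off weights

The log functional fitness of a specimen at position z̄ under mixing weight
w is ln of [w·F₁(z̄) + (1−w)·F₂(z̄)] divided by the maximum of
w·F₁ + (1−w)·F₂ over a reference grid, the maximum recomputed per w. The
estimator scans w over a uniform grid (default resolution 0.001): the inner
maximum switches cells as w moves, so the objective is piecewise-smooth and
can be multi-modal, and smooth optimizers are not trustworthy here. Values
of w whose objective ties the maximum within 1e-12 are reported as a tie
with the midpoint of the tying set — note that a specimen sitting exactly on
the scaled-F₁ maximum ties over an entire interval ending at w = 1, so the
reported w is that interval's midpoint, not 1.

The reference grid defaults to the same grid the surfaces were fitted on
(the 8×8 theoretical grid); the dense 40×40 surface uses itself as reference
unless told otherwise. Which convention the original analyses used is not
recoverable, so both are exposed and recorded.

An important structural property, relied on throughout testing: the
estimated w of "generalist" specimens (far from every performance peak)
collapses onto a small number of atoms — the w values where the Pareto
frontier of (F₁, F₂) over grid cells switches vertices — so empirical w
distributions are heavily clustered even when positions vary continuously.
This mirrors the clustered species weights seen in real systems.

## Sliding-window disparity

Windows of size 0.011 advance by 0.0002 over the data-driven range of the
40×40 w surface; membership is half-open [start, start+size) so adjacent
non-overlapping windows never double count. Per window the analysis reports
the w volume (cells in the window) and, when at least two species fall in
it, the observed disparity: species are clustered on their 2D landscape
positions by full-covariance Gaussian mixtures (K = 1..min(5, n−1), BIC
selection, seeded), and the sum of univariate variances of the full shape
variables is accumulated per cluster (singleton clusters contribute 0). The
clustering prevents species with similar w but from distant morphospace
regions from inflating a window's disparity.

The mixture covariance is regularized by 1e-6 plus 1e-3 of the mean
coordinate variance. A purely absolute floor is scale-dependent: on
unit-scale coordinates it permits two- and three-point components with
near-singular covariances whose inflated likelihood makes BIC split clean
single clusters. The relative term removes that failure mode at any
coordinate scale; the absolute term still absorbs the identical-point
degeneracy. With ~10 diffuse points, BIC over unconstrained mixtures can
still prefer K > 1 — an inherent small-sample property of the selection
rule, not corrected here.

The ξ (Chatterjee) coefficient is computed from the stated formula
1 − 3·Σ|r_{i+1} − r_i|/(n²−1) after sorting by x (x-ties broken uniformly at
random with a recorded seed; y-ranks are "max" ranks), with the one-sided
p-value from the asymptotic null √n·ξ → N(0, 2/5).

## PLS transfer

The first singular triplet of the cross-covariance between centered shape
variables and centered, unit-variance functional metrics gives the axis
pair; only the first pair is used. The sign convention makes the first
functional loading positive. The major axis is the leading principal axis of
the training-group score cloud; transfer specimens are projected onto it
without refitting, and predictions are back-transformed through the shape
axis. Residuals are Euclidean distances in tangent-space shape coordinates,
which agree with Procrustes distances to first order. The group comparison
(two-sided Mann–Whitney on residual distances) is reported descriptively
alongside the medians, not used as a gate. Because the model is fitted on
one group, training residuals are expected to be slightly smaller than
transfer residuals even under a shared mapping (overfitting direction);
synthetic checks therefore compare median ratios against simulation, not
against 1.

## Comparative methods

Trait-model covariances: BM uses shared root-to-MRCA path lengths; EB
rescales through (e^{rt} − 1)/r with r ≤ 0 (r → 0 recovers BM); OU uses the
stationary covariance e^{−α·d}/(2α) on patristic distances d and is
restricted to ultrametric trees — non-ultrametric input is an error, not an
approximation. Maximum likelihood profiles out the rate and root state
analytically; the remaining shape parameter is optimized by bounded L-BFGS-B
from five deterministic starts spanning α ∈ [1e-8, 50/depth] or
r ∈ [−10/depth, 0). Model support uses AICc with k = 2 (BM) or 3 (OU, EB).

PGLS whitens through the Cholesky factor of the BM covariance; r² pools GLS
sums of squares over response columns, and significance comes from seeded
permutation of the whitened intercept-only residuals (999 by default).
Intercept-only, linear and quadratic designs are compared by AICc. PIC uses
the standard pruning recursion (polytomies resolved with zero-length
branches); the Mantel statistic is the unnormalized cross-product of upper
triangles with label permutation; phylogenetic PCA decomposes the
GLS-weighted evolutionary covariance about the phylogenetic mean. External
variable-rates software output is ingested as tip/branch rate tables and
related by raw, tip-level and PIC-transformed correlations (through-origin
convention for contrasts). Multivariate penalized-likelihood model fitting
and MCMC variable-rates estimation are out of scope by design; rate tables
are inputs, never computed here.

## Synthetic studies

`gen_study` draws a unit-depth pure-birth tree, evolves each landmark
coordinate as independent Brownian motion along it (default 35 landmarks,
100 tips, rate 5e-4 — chosen so that tip shape variation is small relative
to the mean shape, as in real cranial data), aligns and ordinates the tips,
builds the extended 8×8 grid, and evaluates two analytic performance
functions with additive Gaussian noise (default sd 0.01 on the scaled
metrics) before min–max scaling. True per-species weights come from a
brute-force scan (step 1e-4) of the noiseless analytic surfaces — an oracle
fully independent of the estimation path. A subtree holding ~25% of tips is
labelled as the transfer clade.

The default performance geometry plants the study-like asymmetry and was
designed mechanistically, once, from the structural analysis above: the
force function F₁ has a narrow peak just outside the occupied morphospace
corner plus two modest generalist components; the velocity function F₂ has a
very local specialist spike in the opposite corner over a broad multi-lobed
plateau. Two consequences matter. First, the F₁ value at the F₂-maximizing
cell is ≈ 0, which is the condition for the bulk of species and cells to
leave the w = 0 atom and settle at an interior kink — without it, most mass
sits exactly at w = 0, where a sliding window sees it only once. Second, the
force basin is small both in cells and in species while the velocity region
is large in both, so the theoretical w-volume profile and the observed
disparity profile co-vary positively, the pattern the windowed analysis is
designed to detect. On six probe seeds the defaults give a force basin of
~360 cells against ~1200 velocity cells, 110–230 disparity-defined windows,
disparity–volume Pearson r between +0.45 and +1.00, and median |ŵ − w_true|
≤ 0.0003 at zero noise and ≤ 0.018 at the default noise.

What the synthetic studies do **not** emulate: measurement error in
landmarks, allometry, modular covariance among landmarks, non-Brownian shape
evolution, and the mesh-level provenance of real functional metrics (the
pipeline consumes scalar values per shape by design). Passing tests
therefore establish the correctness and internal consistency of the
estimators under known ground truth, not the biological fidelity of any
particular surface geometry.

## Problem sizes in the test suite

The suite runs the full pipeline at 100 tips with an 8×8 fitting grid and a
40×40 w surface; replicated simulations use 20–100 replicates (trait-model
recovery 20 replicates at 60 tips; surface-selection 100 draws; PLS transfer
50 seeds; OU covariance 200,000 Monte-Carlo paths on a 4-tip tree). These
sizes were chosen to keep each property decisively testable while the whole
suite completes in well under a minute of compute per module.

## Known limitations

* OU fitting is stationary-only and requires ultrametric trees.
* Kriging assumes second-order stationarity; with 64 training points the
  variogram fit is crude, and the family is usually outperformed by TPS in
  cross-validation.
* The w estimator's atom structure means small surface perturbations can
  move a specimen between neighbouring atoms; recovery error is therefore
  bimodal (usually ~0, occasionally one atom spacing).
* BIC over unconstrained Gaussian mixtures over-segments small diffuse
  windows (see above).
* The PGLS permutation test permutes whitened null residuals, which is exact
  for exchangeable errors under BM but approximate otherwise.
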