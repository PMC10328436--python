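# Methods

This note documents the statistical model behind `gccasub`, the numerical
choices its implementation makes, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Shared representation: GCCA and its deep extension

Given V views `X_v ∈ R^{d_v×N}` on the same N samples, generalized canonical
correlation analysis seeks an orthonormal-row representation `G ∈ R^{r×N}`
and per-view projections `U_v` minimizing `Σ_v w_v ‖G − U_vᵀY_v‖_F²` subject
to `GGᵀ = I`. With ridge-regularized covariances `C_v = Y_vY_vᵀ + ρI` the
optimum is closed-form: rows of `G` are the top-r eigenvectors of
`M = Σ_v w_v Y_vᵀ C_v^{-1} Y_v`, and `U_v = C_v^{-1} Y_v Gᵀ`. Eigenvalues of
`M` lie in `[0, V]`; a value near V marks a direction reproduced by every
view. In the deep variant `Y_v` is the output of a per-view two-layer network
(ReLU hidden layer, linear output layer) trained by full-batch gradient
descent on the GCCA objective using the envelope gradient
`∂J/∂Y_v = 2 w_v (U_vU_vᵀY_v − U_vG)` evaluated at the per-step optimum.

Defaults (exposed in `GccaConfig` / `ViewNetworkConfig`): 500 hidden units,
100 output units, r = 100, view rank 100, ρ = 1e-6, equal view weights,
L1 = 1e-3 and L2 = 1e-4 on all weight matrices (not biases), 20 epochs.
These are the constants a practitioner would use for cohort-scale bulk
multi-omics; all are configurable.

### Numerical choices

- **Centering.** Network outputs are centered per row over *present* samples
  inside every solve; covariance-based CCA is meaningless without it.
- **Missing views.** A sample absent from view v contributes a zero column
  to `Y_v` and is excluded from that view's covariance, centering and
  residual. The eigenproblem is solved on `D^{-1/2} M D^{-1/2}` with
  `D = diag(Σ_v w_v · present(s, v))`. With complete data this is an exact
  rescaling (G unchanged); with missing views it prevents samples observed
  in fewer views from being shrunk toward zero in the embedding, a bias we
  measured at roughly the ratio of observed-view counts. Reported
  eigenvalues are Rayleigh quotients of `G` with respect to `M` itself
  (exact eigenvalues whenever presence is complete).
- **Determinism.** Eigenvector signs are fixed by the first-nonzero-positive
  convention and ties broken by stable ordering, so a seed fully determines
  every downstream artifact.
- **Learning rate.** The full-batch update uses the mean per-sample gradient
  (`grad/N`) with default learning rate 1e-2, keeping the step size
  comparable across cohort sizes. Raw-sum gradients at this rate destroy
  genuine shared signal within an epoch at n ≈ 300 (the networks fabricate
  correlations — every eigenvalue of M is driven to V — a well-known
  overfitting mode of deep CCA when parameters vastly outnumber samples).
  With mean gradients the 20-epoch schedule refines, rather than replaces,
  the random-feature representation of the initial networks.
- **Linear output layer.** Only the hidden layer carries the nonlinearity,
  so the GCCA loss sees an unconstrained range; with identity activations
  and zero penalties the trained model reproduces the closed-form linear
  optimum (verified within 5%).

## Outcome-guided clustering

Each embedding coordinate is screened by a univariate Cox
proportional-hazards model. The p-value is the **score test at β = 0** with
Efron handling of ties — for a group indicator this is exactly the log-rank
test, and it requires no iterative fit; the reported β comes from Newton
iterations on the Efron partial likelihood (step clipping and a |β| ≤ 20
stop guard against monotone likelihoods). Coordinates with p < 0.05 are
retained, with no multiple-testing correction by default (a
Benjamini–Hochberg option exists); at r = 100 this admits ~5 false-positive
coordinates on average, which is intrinsic to the per-coordinate rule and
is why downstream diagnostics matter.

k-means uses uniform random-point initialization, best of 100 restarts by
inertia, up to 2000 iterations. The number of clusters is chosen by
comparing each k's Calinski–Harabasz score with the **median CH of k-means
on standard-Gaussian reference data of the same shape** (15 seeded draws):
raw CH is not comparable across k in low dimension — splitting plain
Gaussians raises it indefinitely, so an argmax rule can report k = 4–6 on a
perfectly planted two-cluster embedding when only a few coordinates survive
the Cox screen. The selected k is the smallest whose CH/null ratio is a
weak local maximum (the gap statistic's decision style), which also
reproduces the two canonical situations: a uniformly decreasing CH profile
yields k = 2, and three well-separated planted blobs yield k = 3. The
diagnostics table reports, per k, the average silhouette, raw CH, null CH,
their ratio, and the fraction of samples with negative silhouette — the
quantity usually judged by eye on silhouette plots.

Prognostic separation uses the k-group log-rank test (lifelines) with k − 1
degrees of freedom and per-group Kaplan–Meier curves exported as step
tables (time, at-risk, events, estimate).

## Subtype classifiers and platform transfer

Per-feature preprocessing learned on training data only: median centering,
then standardization by the mean/sd of the centered training values
(sd = 0 features pass through centered and are flagged). Equal-frequency
bins are cut at the i/B linear-interpolation quantiles of the standardized
*training* values; duplicate edges from ties are merged (fewer effective
bins), and an edge at or below the training minimum is dropped so constant
features occupy bin 1. External data is mapped by the *training* transform
and placed into the *training* bins (below-range → bin 1, above-range →
bin B, interior half-open `[e_{i−1}, e_i)`). Because the whole chain is a
per-feature strictly monotone map, bins depend on ranks only: a platform
distortion that is monotone per feature and removed by the standardization
leaves the ordinal matrix unchanged — the property that makes, e.g.,
RNA-seq → microarray transfer possible. Binning both cohorts on one common
standardized scale (rather than binning raw centered training values) is
required for that guarantee and is what this implementation does.

Feature selection ranks binned features by random-forest importance, then
evaluates a doubling grid of feature counts by repeated stratified CV
(10 folds × 10 repeats by default); the chosen count is the smallest whose
mean accuracy is within one standard deviation of the best mean — a
mechanical elbow rule. The final classifier is XGBoost, tuned by a
sequential model-based search (Matérn-5/2 Gaussian process surrogate,
expected improvement, 10 seeded random initial points, default budget 50)
over learning rate (log 0.01–0.3), depth (2–8), tree count (log 50–400),
subsample and column-subsample fractions (0.5–1), and minimum child weight
(1–10); the objective is mean stratified 10-fold CV accuracy, with
out-of-fold AUC (one-vs-rest macro for k > 2) recorded alongside. Single
threaded tree construction keeps refits bit-reproducible.

## Synthetic cohorts

The generator plants K subtypes at pairwise latent distance
`cluster_separation` (scaled simplex) in a `latent_dim`-dimensional space;
each view observes `A_v softplus(B_v h)` on a `shared_signal_frac` fraction
of its features (fixed random mixing per seed, softplus so the generative
map is genuinely nonlinear) plus Gaussian measurement noise, and pure noise
on the rest. Survival is exponential with hazard
`baseline · hazard_ratio^(cluster−1)` under independent uniform censoring
whose horizon is solved numerically from the closed form
`P(censored) = (1 − e^{−λu})/(λu)` mixed over clusters. Whole views are
dropped per sample at `missing_view_rate`, always retaining at least one.
Defaults: n = 300, K = 2, view dims (2000, 1500, 200), latent dim 10,
separation 8, shared fraction 0.3, noise sd 0.5, 10% missing views, HR 3,
30% censoring. The platform-shift generator redraws samples from the same
process, keeps a random `overlap_frac` of one view's features, and applies
`x → a·x + b + c·tanh(x)` per feature with |c| < a (strictly monotone) plus
fresh noise.

What the generator does **not** emulate: library-size and GC effects,
β-value bimodality, batch structure within a cohort, informative censoring,
or subtype proportions far from uniform. Passing tests therefore certify
the pipeline's statistical machinery under its own assumptions
(proportional hazards, shared low-rank structure, monotone platform
effects), not robustness to every artifact of real TCGA-scale data.

## Problem sizes used in tests

The reference end-to-end fixture runs the full default pipeline on one
seeded cohort at the defaults above (n = 300, dims 2000/1500/200); solver
and gradient checks use small dense problems (N ≤ 25) where oracles are
exact; pipeline-orchestration tests use a reduced cohort (n = 120, dims
60/50/40, 5 epochs, embedding dim 10) chosen so the whole suite re-runs
quickly on a laptop. Across repeated draws of the reference conditions the
end-to-end stage selects k = 2 in ~19/20 seeds and recovers the planted
partition with ARI typically 0.75–0.95; the residual spread comes from the
~5 chance coordinates the per-coordinate P < 0.05 screen admits alongside
the single genuinely discriminant coordinate of a two-cluster cohort.

## Known limitations

- The score-test p-value and the Wald p-value of the Cox fit can disagree
  at extreme effect sizes; the score test is used by design (log-rank
  equivalence).
- With missing views, the envelope gradient treats the normalized
  eigenproblem's G as optimal for the masked objective; the mismatch is
  O(ρ) + O(normalization coupling) and only affects training-step
  direction, not the reported solution (finite-difference agreement is
  verified on complete-presence fixtures).
- `filter_missingness` applied twice is idempotent only when survivors sit
  clearly below the thresholds; re-evaluating fractions over surviving
  samples can drop borderline features on a second pass.
- k selection is only as good as its diagnostics: when the Cox screen
  retains a single coordinate, CH-based selection of any flavour is fragile;
  the null-referenced rule is markedly more stable than raw argmax but not
  infallible on ambiguous data.
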