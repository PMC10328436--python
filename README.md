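# gccasub

Outcome-guided molecular subtyping from multi-omics data.

`gccasub` is for researchers who have several -omics views (bulk expression,
promoter methylation, miRNA abundance, ...) measured on the same patients,
plus survival follow-up, and who want molecular subtypes that (a) reflect
signal *shared across* the views rather than noise private to one platform,
and (b) stratify patient outcome.  It also trains per-omics classifiers that
carry the discovered subtype calls to external cohorts — including cohorts
measured on a different platform — via rank-preserving discretization.

## The method

**Stage 1 — clustering.** Each view `X_v ∈ R^{d_v×N}` is passed through a
two-layer fully connected network `f_v`; the network outputs are tied
together by the generalized canonical correlation analysis (GCCA) objective

```
min_{U_v, G}  Σ_v ‖ G − U_vᵀ f_v(X_v) ‖_F²    subject to  G Gᵀ = I ,
```

whose solution for fixed networks is closed-form: the rows of the shared
representation `G` (r × N) are the top-r eigenvectors of
`M = Σ_v Y_vᵀ (Y_v Y_vᵀ + ρI)^{-1} Y_v` with `Y_v` the centered network
outputs. The networks are trained by full-batch gradient descent on this
objective (the deep extension of GCCA), so that `G` captures the strongest
patterns seen *consistently in every view*. Samples with missing views are
retained: absent sample-view pairs are simply masked out of the per-view
covariances and residuals.

Each of the r embedding coordinates is then screened with a univariate Cox
proportional-hazards model — the p-value is the score test of β = 0, which
is the log-rank-type statistic — and coordinates with p < 0.05 are kept.
k-means (100 random restarts, up to 2000 iterations) clusters the retained
coordinates; the number of clusters is chosen from silhouette and
Calinski–Harabasz diagnostics (CH referenced against a same-shape Gaussian
null, see `docs/methods.md`), and the prognostic separation of the final
subtypes is quantified with Kaplan–Meier curves and the k-group log-rank
test.

**Stage 2 — classification.** On one view, features are median-centered and
standardized with *training* moments, cut into B equal-frequency bins at the
training quantiles, pruned by random-forest recursive feature elimination
under repeated 10-fold cross-validation, and fed to an XGBoost classifier
tuned by sequential model-based (Gaussian-process expected-improvement)
search. External cohorts are pushed through the *stored* scaler and the
*training* bins, so any per-feature monotone platform distortion that the
standardization removes leaves the ordinal representation — and hence the
subtype calls — unchanged.

A first-class synthetic-cohort generator (`gccasub.simulate`) plants
subtype-structured latent signal across views, cluster-dependent exponential
survival with calibrated censoring, missing views, and platform-shifted
external cohorts, so the entire pipeline is testable without any downloads.

## Worked example

`examples/simulate_and_cluster.py` simulates a 200-patient cohort with two
planted subtypes (hazard ratio 3) over three views, then runs stage 1:

```
cohort: 200 samples, 3 views, 69 missing sample-view pairs
Cox screen kept 2/50 coordinates
 k  avg_silhouette  ch_score  ch_null  ch_ratio  frac_negative_silhouette  inertia
 2           0.397   131.743  105.985     1.243                     0.000    1.201
 3           0.395   152.880  130.632     1.170                     0.015    0.784
 ...
chose k=2; ARI vs planted truth = 0.921; log-rank chi2=51.2 (p=8.43e-13)
```

Two of the fifty embedding coordinates carry survival signal; the
null-referenced CH ratio peaks at k = 2; the recovered clusters agree with
the planted truth (adjusted Rand index 0.92) and separate survival
decisively.  `examples/platform_transfer.py` continues into stage 2 and
prints

```
130 of 200 features shared with the external platform
RF-RFE kept 1 features (best CV accuracy 0.985)
training CV accuracy 0.970, AUC 0.986
external accuracy vs planted truth: 0.890; log-rank p on predicted subtypes: 3.11e-10
```

— the subtype calls survive a 65% feature overlap and strictly monotone
per-feature platform warps.  `examples/gcca_closed_form.py` is a minimal
demonstration of the closed-form solver and how eigenvalues of `M` near the
number of views flag genuinely shared directions.

## Command line

The same stages are available as a thin CLI:

```bash
gccasub simulate --seed 3 --outdir cohort/
gccasub cluster  --config run.yaml --seed 3 --outdir results/
gccasub classify --config run.yaml --assignments results/assignments.tsv --outdir results/
gccasub validate --archive results/classifier.pkl --external-view ext.tsv \
                 --external-survival ext_surv.tsv --outdir results/
```

Exit codes: 0 success, 2 configuration error, 3 data error.

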