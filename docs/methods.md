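# Methods

This note documents the models, numerical choices and limitations of
`itemrsa`, in the spirit of a statistical software vignette. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Model RSMs and their overlap

Feature norms are a nonnegative concept × feature matrix of normalized report
frequencies with a category label (visual or semantic) per feature. The model
RSM for a category correlates (Pearson) concepts' vectors over that
category's features; a concept with zero variance over a category block is a
hard error naming the concept, never a silent NaN.

RSM–RSM comparison uses Spearman rank correlation (globally over the
vectorized strict lower triangle, row-major; item-wise over matching rows
with the self cell removed), whereas feature-vector and voxel-pattern
correlations are Pearson. The two conventions are deliberate: rank
correlation for matrix-level overlap, product-moment for vectors on an
interval scale.

Mutual residualization regresses each RSM's off-diagonal vector on the other
(with intercept) and refolds the residuals symmetrically, leaving an
undefined diagonal. For standardized vectors with correlation r, the two
residual vectors have correlation exactly −r (corr(x − r·y, y − r·x) = −r);
the test suite verifies this identity at r ∈ {0.2, 0.5, 0.8} to 1e−10. The
granularity of residualization is ambiguous in principle (whole-matrix vs
per-item-row), so both are provided; whole-matrix is the default and per-row
is a flag. No claim is made about which granularity produces any particular
published overlap value.

## Single-trial GLM

The hemodynamic response is the canonical double gamma: a positive gamma
density (delay 6 s, dispersion 1 s) minus a late undershoot (delay 16 s,
dispersion 1 s) divided by a peak:undershoot ratio of 6, peak-normalized.
These are conventional community defaults and fully configurable. Trial
regressors evaluate the continuous kernel at scan times relative to each
onset, so onsets need not be scan-aligned, and the synthetic BOLD generator
uses the identical regressor construction — which is why noiseless
round-trip recovery of true betas is exact to numerical precision (< 1e−6
asserted).

All trials are estimated simultaneously in one OLS model per voxel, with
nuisance regressors accepted as given numeric columns plus an intercept.
A rank-deficient design raises an explicit error; there is no silent
pseudo-inverse fallback. High-pass filtering, slice-timing and motion
correction are out of scope: inputs are assumed preprocessed.

## APMs, trial exclusion, temporal correction

The APM Pearson-correlates voxel patterns of all valid trial pairs. Excluded
are catch trials, encoding trials with a don't-know/no-match press, and — in
retrieval — any item so flagged at encoding. The time RSM scales within-run
onset distance to [0, 1] (1 = same time, 0 = furthest apart within the run);
cross-run cells are 0 because runs share no scanner drift, and a run with a
single valid trial contributes zeros. Temporal correction regresses the APM's
lower-triangle cells on the time RSM's (with intercept) and keeps the
residuals without re-adding the intercept — downstream IRAF uses
correlations, which are shift-invariant. A constant temporal predictor
degenerates to mean-centering with a logged warning.

## IRAF

For each item, the IRAF is the Pearson correlation between the item's
(time-corrected) APM row and its model-RSM row, self-similarity excluded from
both vectors (the diagonal is constant in the model and residual-corrected in
the APM, so it is uninformative and scale-breaking). Items present in the APM
but absent from the model (novel retrieval foils) are dropped from the
vectors automatically. Raw correlation is the default statistic; Fisher z is
available by flag and is verified to be strictly monotone in r. Degenerate
(constant-row) items are dropped with a logged count, never imputed. An
optional flag excludes within-run pairs from the vectors; the default retains
all off-self cells.

## Behavioral adjustment

Confidence 1–4 collapses to old ({3,4}) vs new ({1,2}). The false-alarm
tendency is each participant's mean response to new items, tested against 2
("probably new") by a one-sample t test, t = (mean − 2)/SE with n − 1 df.
p values are two-sided — the packaged reference table reports p = .001 for a
*negative* t, which a one-sided greater-than test cannot produce — and the
bias flag additionally requires mean > 2, making the flagging one-sided in
effect. For flagged participants, "probably old" responses to old items are
demoted to forgotten; "definitely old" is never demoted, so adjustment is
monotone. Valid-trial counts are fixed by the exclusion rules and unaffected
by demotion. The packaged 19-participant summary table reproduces a group
adjusted hit rate of 0.62 (SE 0.03), and recomputing each t from its printed
mean and SE matches the printed t within ±0.05 (printed-input rounding).

## Mixed models

The engine (`itemrsa.lmm`) fits y = Xβ + Σ_k Z_k u_k + ε with crossed random
intercepts by profiled REML. Variance ratios γ_k = σ_k²/σ² are optimized on
the sqrt scale with nonnegativity bounds (L-BFGS-B, fixed start 0.5);
the Woodbury identity reduces each objective evaluation to O(q³) in the
total number of random levels, making ~23,000-observation fits take well
under a second. β and σ² are profiled out analytically.

Type III F tests use sum-to-zero contrasts — Type III sums of squares are
coding-dependent, and deviation coding makes each term's hypothesis the
vanishing of its own coefficients in the full model. Denominator degrees of
freedom use the Satterthwaite approximation: for a contrast ℓ,
df = 2φ²/Var(φ) with φ = ℓ'C(θ)ℓ, the gradient of φ taken by central finite
differences in the variance components and Var(θ̂) from the finite-difference
Hessian of the REML deviance. Multi-df tests pool per-eigenvector one-df
values as lmerTest does (E = Σ ν_i/(ν_i − 2), df = 2E/(E − rank)). When the
variance of φ is not estimable (boundary fits, singular Hessians) the code
falls back to the residual df n − p with a log entry; large-n F tests are
insensitive to the choice. The engine reproduces lmerTest's estimates,
standard errors, Satterthwaite df, F and REML log-likelihood on a crossed
two-factor dataset to the printed precision (asserted in the suite via
Rscript).

Non-converged fits are flagged honestly and excluded from the per-ROI
summary with a log entry; no silent refitting with simplified structure is
attempted. FDR correction is Benjamini–Hochberg across the full family of
ROIs × fixed-effect terms. Note that BH adjustment is *not* idempotent
(re-adjusting adjusted values can only increase them); the suite asserts
order-invariance, monotonicity and q ≥ p instead.

Post hoc contrasts are marginal (least-squares) mean differences, remembered
− forgotten within each phase, averaging model cell predictions over the
remaining factors, each with a Satterthwaite t test. ROIs with a significant
positive retrieval contrast are sorted into *retrieval-success* vs
*encoding–retrieval flip* by the encoding contrast; the encoding threshold is
configuration (`FlipRule.enc_t_threshold`, default 0, i.e. any numerically
negative encoding contrast counts as a flip) because published t patterns do
not pin down a unique rule. The planted-recovery tests use a threshold of
−2 to separate a true flip (strongly negative encoding t) from a
retrieval-only effect (encoding t near 0).

The area model submits remembered-trial IRAFs from IPC and OTC ROI groups to
phase × area with random intercepts for feature type, participant, stimulus
and ROI. A two-level grouping factor as a random intercept is statistically
unusual; a switch treats feature type as fixed instead.

### Power analysis

`power_sim` simulates response = d·condition + participant intercept + item
intercept + residual over the full participant × item × phase × type grid
(condition split along the phase factor), fits the crossed model and tests
the condition effect. Random-intercept SDs default to 0.1 (participant) and
0.1 (item) in residual-SD units — no empirical values being available, these
are small-but-nonzero conventions, exposed as arguments. Under the reference
design (19 × 300 × 2 × 2, d = 0.4, α = .05) estimated power is at the
ceiling; the acceptance script reports it from 60 replicates.

## Decoding

Per ROI, each training sample is one item's scalar IRAF labelled by feature
type (the minimal sample definition consistent with per-ROI decoding; a
multi-ROI vector mode is available through the same function by passing 2-D
samples). A linear SVM with fixed C = 1 trains on encoding samples and is
scored on retrieval samples — no cross-validation within phase, no
hyperparameter search. Chance is established by simulating participants
whose features carry no label information; the observed correct/incorrect
totals are compared with the null-expected split by a 1-df chi-squared test.
The null draws are returned so an empirical-quantile test can be used
instead of the chi-squared construction.

## Synthetic-data generator

The generator's defaults mirror the reference study design: 19 participants,
300 old objects, 60 catch items, 100 novel retrieval foils, two encoding
runs, TR 2 s, 2–7 s jittered ITIs, an 8% don't-know rate at encoding. The
latent memory strength θ_i ~ N(0.45, 1) drives both the confidence response
(binned at thresholds −1/0/1 after adding response noise and bias) and the
outcome used to plant pattern weights, keeping behavior and neural planting
consistent; the mean of 0.45 puts the expected hit rate at
Φ(0.45/√2) ≈ 0.62, matching the reference behavioral summary.

Feature values are rectified Gaussians, column-normalized, with the semantic
block a convex mixture (weight = `cross_corr`) of duplicated visual features
and fresh draws — giving a monotone, tunable RSM overlap with exact identity
at `cross_corr = 1`. Voxel patterns are random projections: per ROI, frozen
i.i.d. standard-normal loading matrices map each item's *centered, unit-norm*
category feature vector to voxels, scaled by planted weights w_v, w_s and
summed with i.i.d. Gaussian voxel noise. Centering before projection makes
the expected voxel-pattern correlation track the feature-vector Pearson
correlation (hence the model RSM) rather than the cosine of raw nonnegative
vectors, which is what gives the pipeline a crisp planted signal: with unit
feature vectors and unit-variance loadings, w/σ is the per-voxel SNR, and a
planted weight gap of at least 3σ/√n_voxels is reliably recovered
downstream. Planted weights are keyed by (ROI class, phase, outcome), with a
specific ROI id overriding its class so one study can contain qualitatively
different ROIs of the same anatomical class (a retrieval-success and a flip
parietal ROI, say). Trials without a memory outcome (catch, novel) receive
the mean of the remembered/forgotten weights.

What the generator does **not** emulate: scanner physics, motion,
physiological noise, spatial autocorrelation, hemodynamic nonlinearity,
heavy-tailed or temporally autocorrelated BOLD noise (the Gaussian i.i.d.
choice is a stand-in, not an inference about real data), letter-probe
stimulus content (catch status is a flag only), or realistic feature-norm
sparsity structure. Passing planted-recovery tests therefore demonstrates
that the *pipeline arithmetic and inference* recover known structure under
the stated noise model — not that the method is robust to every artifact of
real fMRI data.

## Validation problem sizes

The heavier end-to-end checks run at deliberately reduced scale, chosen once
as the smallest designs where the planted effects sit comfortably above
their recovery thresholds: planted-pattern recovery uses 8 participants × 30
old items × 3 ROIs × 60 voxels per ROI across 100 seeds (weight gaps
0.55–0.6 per-voxel SDs against a 3σ/√60 ≈ 0.39 threshold); Type I
calibration uses 8 participants × 20 items × 2 × 2 with random-intercept SDs
0.3 over 500 replicates, pooling the seven fixed-effect tests; the power
bound runs the full 19 × 300 × 2 × 2 design for 50+ replicates, which the
O(q³) REML engine makes cheap.

## Known limitations

* Random intercepts only — no random slopes, no Kenward–Roger df, no
  Bayesian fitting.
* Satterthwaite df relies on finite-difference derivatives; for fits on the
  variance boundary the residual-df fallback is used (and logged).
* The IRAF is a correlation of correlations; its sampling distribution is
  item-dependent, and the mixed model treats it as a plain response.
* The chi-squared chance test assumes independent trials within the pooled
  totals; the empirical null quantiles are the safer alternative for small
  samples.
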