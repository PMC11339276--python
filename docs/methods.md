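# Methods

`patsep` implements a multivariate analysis chain for event-related fMRI of
the macaque face-processing hierarchy (areas ML → AL → AM) under a
statistical-learning paradigm, together with a synthetic study generator that
plants known representational geometry so every stage can be validated
against ground truth. This note documents the models, the statistics, the
generator's assumptions, the numerical choices, and what the synthetic
validation does and does not establish.

## The paradigm being modeled

Eighteen facial identities, each rendered at three trained views (frontal,
left profile, right profile), are split into nine predictor–successor pairs
with head orientations balanced within roles. After statistical learning the
predictor fully predicts the successor. The test phase presents pairs at
exact proportions of 60% expected successors, 20% unexpected-identity
violations (the trained successor image of a *different* pair — never a novel
identity), and 20% unexpected-view violations (the expected identity at one
of four untrained orientations). Stimuli last 500 ms; intra-pair baselines
are jittered over {1.5, 3.5, 5.5} s and inter-pair baselines over
{5.5, 7.5, 9.5} s, so every onset falls on a 2-s TR grid. Condition counts
are allocated exactly (not Bernoulli-sampled) so design proportions are
testable as identities, and training sequences keep within-pair transition
probability at 1 while balancing between-pair transitions greedily.

Three analysis conditions follow from the design: **context-free** (the nine
predictor faces, which cannot be anticipated), **expected** (the nine trained
successors after their predictors), and **unexpected** (the same successor
images presented as violations).

## Synthetic stimuli and ground-truth pattern geometry

Each identity carries a 68-landmark shape vector (136 coordinates) and a
50-dimensional appearance vector. View deformation is a smooth function of
signed head angle — one random field scales with sin(angle), one with
1 − cos(angle) — so opposite turns displace landmarks in opposite directions
and the frontal view is undeformed. Appearance picks up an additive view
component that is zero at the frontal view, making the frontal appearance the
identity's canonical appearance. Identity features for successors are an
orthogonal rotation of the predictor features, so the two role sets have
identical feature-space Gram spectra — the stimulus balance the paradigm
requires (and which `stimulus_balance_check` verifies with a two-sample t on
within-role pairwise distances; nine stimuli per role give df = 70). Images
are rendered deterministically from landmarks and appearance (Gaussian bumps
on a 32×32 canvas), mean-luminance equalized, and left/right profiles are not
pixel mirrors (an identity-by-view jitter breaks the symmetry).

Voxel patterns for one ROI × condition cell are built as follows:

1. **Tuning read-out.** Feature vectors for the selected tuning models
   (view-specific shape = landmarks; mirror-symmetric = canonical appearance
   plus a view code shared between the two profiles; appearance =
   view-bearing appearance; view-invariant appearance = canonical appearance
   regardless of displayed view) are centered across stimuli and embedded in
   voxel space through *orthonormal* random projections. The isometry
   preserves the feature Gram exactly, so a cell's true geometry does not
   depend on the projection draw; in particular two conditions with the same
   tuning have exactly equal participation ratios in the noiseless limit.
2. **Context dimensions.** Orthogonal condition-specific axes with
   per-stimulus coefficients, scaled to the typical dominant eigenvalue of
   the existing geometry so k axes raise the participation ratio by roughly
   k. The coefficients are shared across ROIs (one predictive-context signal
   reaching every area; the voxel axes remain ROI-specific).
3. **Shared top-down component.** Receiving areas blend in (weight 0.5 in the
   expected/unexpected conditions) a latent carrying the view-invariant
   appearance geometry of the successor faces — the representational format
   of the top of the hierarchy. AM, the source of that format, does not
   blend it (a no-op by construction).
4. **Separability calibration.** A common-mode unit vector m is mixed with
   the unit-normalized stimulus-specific part z_i as x_i = m + c·z_i, and c
   is solved by bisection so the circular-mean pairwise angle hits the target
   within ±2° in the noiseless limit (unreachable targets raise an error).
5. **Measurement noise.** Per-voxel Gaussian noise of standard deviation
   noise_sd/√n_trials (the patterns stand for trial-averaged t-statistics;
   defaults noise_sd = 0.4, n_trials = 36). The structural stream (projections,
   context axes) is seeded per ROI and shared across conditions — an ROI keeps
   its voxels — while noise is re-drawn per condition.

Default geometry (the study conditions): context-free ML = shape at 52°,
AL = mirror-symmetric at 68°, AM = view-invariant appearance at 85°; expected
ML = mirror-symmetric at 61° + 6 context dims, AL = appearance/view-invariant
mix at 77.2° + 6 context dims, AM unchanged. The unexpected condition is
built as the expected geometry (fresh noise) plus a prediction-error
component with the next-higher tuning per area, scaled by pe_gain = 1.3, so
that matched differences unexpected − expected genuinely carry the planted PE
tuning and separability/dimensionality rise further in the lower areas.

## Trial-wise GLM (least-squares-single)

BOLD runs are simulated as HRF-convolved sticks carrying each trial's pattern
as its beta, with AR(1)+white noise. The estimator fits one GLM per trial:
the trial-of-interest regressor, a single regressor collapsing all other
trials, optional nuisance columns, and polynomial drift up to degree 2 (the
first volumes can be dropped before fitting). The trial statistic is
beta / SE(beta) against the implicit baseline. The canonical double-gamma HRF
(peak ≈ 5 s, unit peak against the continuous-time maximum, so TR sampling is
an exact subsample of the fine grid) is built from scipy gamma densities.

With non-overlapping trials and no shared drift columns, LSS is algebraically
identical to a one-shot GLM with separate trial regressors — the oracle used
in the tests. Under the rapid design trials overlap and the collapsed-others
model is deliberately mis-specified; single-trial amplitudes are then biased
(a known LSS property), but the multivariate *pattern* per trial — all that
downstream geometry analyses consume — is recovered faithfully (median
pattern correlation well above chance in the pipeline's GLM stage).

Noise covariance is estimated from the pooled trial-GLM residuals with
Schäfer–Strimmer analytic shrinkage toward the diagonal (fMRI ROIs can have
more voxels than residual degrees of freedom), and patterns are whitened by
the inverse symmetric square root — basis-independent, and idempotent on
already-white data.

## Separability and circular statistics

Separability between stimuli i and j is θ_ij = arccos(cos-similarity) of the
whitened pattern vectors, in degrees within [0, 180]; nine stimuli give 36
pairwise angles per cell. Angles are treated directly as circular data (no
axial doubling; doubling changes none of the planted-recovery conclusions and
the reported df structures match the direct treatment). Tests:

- **Watson–Williams** F for independent samples, F with df (1, N−2) and the
  standard concentration correction K = 1 + 3/(8κ̂); a validity warning is
  attached when the pooled within-sample resultant length drops below 0.45.
- **Paired Hotelling** on unit-circle pair differences
  (cos a − cos b, sin a − sin b): one-sample T² against the origin, F with
  df (2, n−2).
- **One-sample mean-angle test** via the chi-square confidence-arc
  construction for the circular mean; the result is a CI decision (the
  statistic is the deviation in units of the CI half-width), not a
  continuous p.
- **Holm** step-down correction (statsmodels), applied per contrast family.

All three hand-built circular tests are calibrated by Monte-Carlo null
simulations in the test suite (empirical type-I in [0.03, 0.07] at nominal
0.05 over 2000 draws).

Population response magnitude is the per-stimulus L2 norm of the
*un-normalized* t patterns (no extra scaling, so genuine amplitude
differences survive); its decoupling from separability is the Spearman rank
correlation across the 9 ROI × condition cells (df = 7). Scaling all patterns
by a constant changes every norm and no angle — magnitude and geometry are
independent by construction.

## Dimensionality

The participation ratio PR = (Σλ)²/Σλ² is computed from the eigenvalues of
the stimulus-by-stimulus covariance of patterns centered across stimuli, so
PR is bounded by the stimulus count. Noise ceilings come from synchronized
permutations (default 1000): each voxel's values are independently shuffled
across stimuli, destroying cross-voxel stimulus structure while preserving
marginals; the one-sided p uses the add-one correction. Condition/ROI
contrasts reference the observed PR difference to the distribution of
differences of the two permuted-PR draws (two-sided, add-one). This null
carries permutation variability only — it presumes the underlying geometries
are stable across conditions, which the generator's isometric embeddings
guarantee for the no-change (AM) cell; with noisy random projections instead,
the same test would flag pure embedding noise, which drove the generator
design choice.

## Representational similarity analysis

1st-level RDMs are cosine distances over whitened patterns (θ = arccos(1−d)
ties them to the separability module exactly). The four model RDMs are
Spearman-correlation distances between feature vectors (shape landmarks;
view-bearing appearance; frontal-only appearance assigned to every view
combination of an identity pair, which is what makes it view-invariant), plus
the binary mirror-symmetry RDM (0 within view and between left/right
profiles, 1 otherwise). The low-level control is a Gabor wavelet pyramid
(4 scales × 8 orientations, energy pooled on a 4×4 grid — orientation
sensitive, tolerant to small translations) turned into a Spearman-distance
RDM.

2nd-level fits are partial Spearman correlations (partial Pearson on ranks)
of the 1st-level RDM with each model RDM, controlling the Gabor RDM; Fisher z
throughout. The bootstrap (default 10,000) resamples *stimuli* — rows and
columns jointly, dropping cells that pair a stimulus with itself — because
RDM cells sharing a stimulus are dependent. The winning-model test compares
the candidate's z against the mean of the other three across bootstrap draws
(one-sided, add-one, ties counted half so identical models sit near 0.5).

Condition contrasts of model fits are dependent, *non-overlapping*
correlation comparisons — the two conditions involve different stimulus sets,
hence four distinct variables — tested with the Raghunathan–Rosenthal–Rubin
statistic (Pearson–Filon covariance of the two correlations, Fisher z,
normal approximation), one-sided in the direction of the planted hypothesis
(higher-order tuning rises in receiving areas, feedforward tuning falls).
The independent-samples analog is Fisher's z test. Both are Monte-Carlo
calibrated in the suite.

Prediction-error geometry takes plain matched differences
unexpected − expected on whitened patterns (the ratio form is deliberately
not the default; plain subtraction is the standard PE-isolation step), then a
cosine-distance RDM over the nine difference patterns and the same 2nd-level
machinery; the Gabor control is omitted for view-violation PEs, whose
image set spans untrained orientations.

## Pattern connectivity

Connectivity between areas is the repeated-measures correlation of 1st-level
RDM cells: observations are the 36 lower-triangle cells per area pair, the
grouping factor is the area pair (within-group centering + pooled Pearson,
df = N − k − 1; with one group this is the ordinary correlation), after both
RDMs are residualized on the rank-transformed Gabor RDM. The
expected-vs-context-free contrast bootstraps face indices jointly in both
conditions (each condition keeps its own control RDM) and reports a
one-sided p for a connectivity increase.

## Pupil entrainment

A 1 Hz image stream of learned pairs has a 0.5 Hz pair frequency; entrainment
of pupil area at 0.5 Hz indexes learning of the pair structure. The pipeline:
linear interpolation of blinks and of median-absolute-deviation outliers
(cutoff 3.5 by default), a one-pass zero-phase Kaiser-windowed sinc FIR
low-pass at 5 Hz (2 Hz transition, −60 dB, odd length so the group delay is
compensated exactly), linear detrend per run and per block, subtraction of
the 2-s pre-block baseline; 32-s pseudo-trials locked to pair onsets with
30-s overlap; DPSS-multitaper spectra at 0.0625 Hz resolution
(NW = T·resolution/2, K = max(1, ⌊2NW−1⌋) tapers, hence a single taper at the
defaults); ITC(f) = modulus of the across-epoch mean of unit-normalized
complex spectra, averaged over tapers, returned on the 0–5 Hz pupil band
(nothing survives the low-pass above it); and the pair-frequency ITC divided
by the mean of its four flanking bins (two above, two below) — values above 1
indicate entrainment. Significance is a one-sided t against 1 across runs;
learning across training is an unpaired one-sided t between the first and
second half of sessions.

The pupil generator writes a slow drift with *irregularly* spaced knots,
image-evoked dilations with habituated mean amplitude (0.3) plus amplitude
and latency jitter, an entrainment component that is a harmonically clean
sinusoid at 0.5 Hz phase-locked to pair onsets, white measurement noise that
dominates single events, and Poisson blinks as NaN dropouts. Blocks hold 16
pairs (32 s — exactly one pseudo-trial) preceded by two warm-up pairs so the
epoch starts in evoked steady state, and pseudo-trials never straddle silent
gaps. These choices are not cosmetic: epochs that cross block edges, kernel
trains at the pair rate, regularly spaced drift knots, or strong un-jittered
image responses each plant spurious phase-locked power on the 2-s grid —
inter-trial coherence is amplitude-blind, so any deterministic structure
above the noise floor at a grid frequency saturates its bin. The default
training length (7200 pair presentations → 400 blocks; monkeys train for
weeks, so this is modest) keeps the coherence floor low enough that the
normalized-ITC spectrum peaks at 0.5 Hz essentially always at
entrainment_strength 1.

## What the synthetic validation shows — and what it does not

Passing tests establish that every estimator and test behaves correctly on
data satisfying its own assumptions, that the planted geometry (separability
hierarchy, condition effects confined to the lower areas, per-area tuning
models, top-down connectivity increase, pupil entrainment) is recovered by
the full chain, and that the statistics are calibrated under their nulls.
They do not establish anything about real macaque fMRI: the generator has no
physiological noise structure beyond AR(1), no motion or distortion, perfect
stimulus timing, Gaussian feature spaces instead of real face statistics, and
a single group (the per-monkey layer of the original analysis is a grouping
column here). Real-data effect sizes, and the published values estimated from
them, are outside what this package can or tries to reproduce.

## Problem sizes and defaults

Defaults follow the design constants above (9 pairs, 60/20/20, 200 voxels
per ROI, noise 0.4/√36, 10,000 bootstrap samples, 1000 permutations,
α = 0.05 with Holm families per contrast). The test suite and the acceptance
script scale stochastic settings (bootstrap/permutation counts, number of
simulated runs) to keep a full validation run in the low tens of minutes on a
single CPU; all scaled settings remain well above the regimes where the
corresponding estimates stabilize in our checks. The full default pipeline
(`patsep run-all`) completes in a few minutes.

## Known limitations

- Angles are treated as plain circular data; axial doubling is available as
  an explicit choice in analyses built on the library but is not a config
  switch of the circular tests themselves.
- The PR condition contrast inherits the noise-ceiling null's assumption that
  the underlying geometry is stable under the no-effect hypothesis; with
  strongly heteroscedastic real data it can be liberal.
- LSS single-trial amplitudes are biased under heavy response overlap; only
  pattern direction should be interpreted at short inter-trial intervals.
- The one-sample mean-angle test returns a CI decision rather than an exact
  p-value; at extreme dispersion it flags itself unusable.
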