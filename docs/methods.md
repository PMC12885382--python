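# Methods

This note documents the models, priors, conventions and numerical choices
behind `sleepprint`, and what the synthetic cohorts do and do not emulate.

## Feature extraction

Recordings are 19-channel (10-20 montage subset), 250 Hz, 900 s: the first
300 s annotated N1 sleep, the remaining 600 s N2.  The pipeline band-pass
filters to 1-45 Hz (zero-phase FIR, 0.5 Hz transition bands, via MNE), cuts
60-s epochs and keeps six canonical ones: N1a/N1b are minutes 0-1 of the N1
block, N2a/N2b minutes 0-1 and N2c/N2d minutes 8-9 of the N2 block — so
N2a+N2b are subsequent in time while N2a+N2d probe segments far apart.

Per epoch and channel a Welch PSD is computed (Hamming window, nperseg =
nfft = 1024, 50% overlap, ~0.244 Hz resolution).  Thirteen analysis bands
span 1-42.6 Hz with widths growing by exactly 0.2 Hz (1-3, 3-5.2, ...,
38.2-42.6 Hz).  Band power is the trapezoidal integral of the PSD over the
band with linear interpolation at the exact band edges; this makes a flat
spectrum yield exactly width-proportional shares (band 1 = 2/41.6) and the
per-channel sum-to-one invariant exact, which a bin-center assignment on
the 0.244 Hz grid cannot achieve.  Relative power divides by the channel's
total power within the 13 bands, removing per-channel amplitude scaling
(e.g., skull/cap effects); the feature vector is channel-major, s = 19 x 13
= 247.  Before model fitting, columns of Y are Z-scored; in
cross-validation the test fold reuses the training fold's parameters to
avoid leakage.  Zero-variance columns get a 1e-12 SD floor with a warning.

## The latent-noise reduced-rank regression

Y (n x s) = (X Psi + Omega) Gamma + E, with X the one-hot subject design.
Priors: Psi entries N(0, 1); Omega entries N(0, sigma_Omega^2) with
sigma_Omega = 0.1 by default — latent noise is assumed small relative to the
subject signal, and the value is configurable because it is a modeling
choice, not an estimated quantity; residual variances sigma_j^2 ~
InvGamma(1, 0.5); rows of Gamma get multiplicative gamma-process shrinkage,
gamma_hj ~ N(0, 1/tau_h), tau_h = prod_{l<=h} delta_l, delta_1 ~ Ga(2.1, 1),
delta_l ~ Ga(3.1, 1), giving stochastically increasing shrinkage of later
components so the effective rank adapts below K.

### Sampler

All full conditionals are conjugate.  One sweep updates, in order: Psi,
Omega, Gamma (column-wise, batched Cholesky), Sigma, and the shrinkage
weights.  Psi is drawn from its conditional with **Omega marginalized out**
(a collapsed/blocked update using the Woodbury identity on
C = Sigma + sigma_Omega^2 Gamma' Gamma): Psi and Omega both explain subject
means, and updating them sequentially from their mutual conditionals leaves
a slow trade-off direction in the chain; the collapsed update removes it,
raising the minimum bulk ESS of sampled Theta entries from tens to several
hundred at 500 retained draws.  Omega is then drawn given Psi, keeping the
stationary distribution intact.

Initialization: Gamma from Fisher's linear discriminant of subjects — the
generalized eigenproblem of between- vs within-subject scatter (ridge
1e-6 x trace/s on the within scatter) gives the top-K discriminant axes,
and Gamma is the least-squares map from the discriminant scores back to
feature space.  The reconstruction map, rather than the weight vectors
themselves, is used because the latent noise shares Gamma's row space:
within-subject covariance is inflated exactly along the signal directions,
which tilts the weight vectors away from the signal subspace while the
reconstruction rows still span it.  When K exceeds the number of
discriminant directions (subjects - 1), remaining rows are filled with top
right-singular vectors of the subject-centered residual.  Psi starts from
the least-squares fit of the subject means, Omega at zero.

Defaults: K = 30, 1000 iterations, 500 burn-in.  Point estimates are means
over retained draws; Theta-hat is the mean of the per-draw products
Psi_t Gamma_t (robust to rotation drift between Psi and Gamma, which are
only identified through their product).  A non-finite residual-variance
draw aborts with the iteration state in the message.

### Diagnostics and PTVE

Split-R-hat and bulk/tail ESS (via ArviZ, single chain split into halves)
are computed for 200 randomly sampled Theta entries; entries with ESS < 100
are flagged, following the usual rule of thumb.  Constant chains are
reported as ESS 0 and flagged.  PTVE = tr(Cov(X Theta-hat)) / tr(Cov(Y))
uses empirical column variances (ddof 1); it is exactly 1 for noiseless
data and 0 for Theta = 0.

### Choosing K

`select_k_elbow` sweeps a K grid with a user-supplied evaluation (typically
whole-data fingerprinting at reduced iterations) and returns the smallest K
whose success-rate gain over the previous grid point drops below one
percentage point (falling back to the best-performing K on a strictly
rising curve).  Identification accuracy is inverse-U in K: below the true
rank the latent space cannot separate subjects; far above it, Gamma's span
admits within-subject noise directions, inflating self distances.

## Fingerprinting conventions

Latent coordinates are Y pinv(Gamma) with the posterior-mean Gamma (the
right pseudo-inverse = least-squares reconstruction coordinates;
rank-deficient Gamma falls back to the minimum-norm solution with a
warning).  Identification is row-wise: segment a of each subject is queried
against all subjects' segment b; prediction = argmin of L1 distance
(argmax of Pearson correlation for the baseline, which uses the raw,
unstandardized relative bandpowers); ties break to the lowest column index
with a warning.  The differentiability Z-score uses the mean and sample SD
(ddof 1) over the N-1 off-diagonal entries of the subject's row, negated
for distances so larger is always more distinct; it needs N >= 3 and emits
NaN with a warning when the other-pair spread is zero.  With mixed-stage
training segments the self pair defaults to the first two same-stage
labels.  Cross-validation partitions subjects (not rows) into 10 folds;
each fold refits the model on training subjects, projects test subjects
with the trained Gamma, and scores identification among test subjects only.

## Group statistics

- **Cluster-level permutation test**: per frequency bin, a one-way
  repeated-measures F across segment labels (subject effects removed);
  bins above the 99th percentile of F(d1, d2) form contiguous clusters
  scored by summed F.  The default threshold dfs are d1 = segments - 1 and
  d2 = n_subjects — the reference convention — with the textbook error df
  (S-1)(n-1) available by argument; the choice only moves the
  cluster-forming threshold and does not affect the validity of the
  max-cluster-mass permutation null (within-subject label permutations,
  p = (count + 1)/(n_perm + 1), default 1000 permutations).  An exact-zero
  guard forces F to 0 where the segment sum of squares is at rounding-error
  level, so identical segments yield no clusters.
- **Mantel test**: matrices are symmetrized (mean of (i,j) and (j,i)),
  off-diagonal upper triangles correlated, rows/columns of one matrix
  permuted jointly; one-sided for positive association, 999 permutations,
  p never below 1/(n_perm+1).  Implemented in-package so that a seed
  controls the permutations; scikit-bio's implementation serves as an
  independent cross-check in the tests.
- **Regressions** (statsmodels OLS): differentiability ~ noise + sex + age
  + cap + noise:sex (plus age:sex for N1-sleep models), with sex = F and
  cap = small as references; the noise covariate is
  |log RMS_seg1 - log RMS_seg2| of per-segment EMG.  Single-level factors
  are reported as aliased terms before fitting.  The total-power (AUC of
  the channel-averaged PSD over 1-42.6 Hz) vs age fit is a cubic
  polynomial with HC3 robust standard errors; artifact-vs-age is a simple
  OLS slope.  Age groups, where needed, are 10 equal-size rank bins.

## The synthetic cohorts

`generate_cohort` draws per-subject parameters deterministically from
(cohort seed, subject index).  Defaults define the study conditions:

- **Ages**: gamma(shape 1.15, scale 4.0) clipped to 0.1-19 y — right-skewed,
  majority under 5 y, mean ~4.6 y.
- **Aperiodic background** 10^offset / f^chi: the offset has an inverted-U
  age profile peaking near 2.5 y (total power rises in infancy, then
  falls); the exponent falls from ~1.8 toward 0.8 with log-age.
- **Peaks**: an alpha-range peak whose center drifts from ~6 toward ~10 Hz
  with maturation, and a 12-15 Hz spindle peak whose amplitude grows with
  age and whose N1 gain is drawn in (0.10, 0.35) against an N2 gain of 1 —
  every subject's spindle power is strictly larger in N2.
- **Idiosyncrasy**: one scale multiplies all stable per-subject deviations
  (channel gains, per-peak spatial profiles, peak centers/amplitudes,
  exponent and offset jitter).  `CohortConfig.exchangeable()` zeroes it
  together with the age couplings, giving statistically exchangeable
  subjects for null calibration.
- **EMG**: broadband 20-120 Hz noise with a fronto-temporal spatial
  profile, per-minute RMS log-normally jittered around an age-decaying
  level; the injected per-segment RMS is recorded exactly in the cohort
  table.  A `wake_contamination` flag can replace random epochs with
  wake-like spectra (peaks suppressed) for robustness checks.

Signals are built per 60-s block by inverse-FFT of complex Gaussian spectra
matching the target PSD exactly (frequency-domain shaping), which makes
spectral properties verifiable in closed form.  The generator does **not**
emulate cardiac/ocular artifacts, mislabeled sleep stages (beyond the
optional wake flag), non-stationarity within blocks, inter-channel
correlation structure, or real electrode geometry — so passing tests show
the *pipeline* behaves correctly under the assumed spectral structure, not
that clinical success rates would match.

## Problem sizes and test design

The test suite and acceptance script run entirely on synthetic data at
desk scale, chosen to keep each check sharp but quick: recovery uses 40
subjects x 2 segments with 60 features and true rank 4 at full sampler
settings; fingerprinting calibration uses 2000 null 20 x 20 matrices and a
30-subject raw-signal cohort through the full pipeline with 10-fold CV;
cluster calibration uses 200 replicates of 30 x 4 x 171 exchangeable PSDs
at 500 permutations; Mantel and regression calibrations use 200 replicates
each.  Monte-Carlo checks compare against 3-standard-error bands or
Kolmogorov-Smirnov uniformity at the 1% level.

## Known limitations

- EDF export is not implemented (recordings and features persist as CSV);
  EDF *reading* for user data goes through MNE.
- Shrinkage hyperparameters (a1 = 2.1, a2 = 3.1) follow common practice for
  multiplicative gamma priors and are exposed in config but not tuned.
- The latent-noise prior scale is a fixed modeling choice, not learned;
  grossly mis-set values (orders of magnitude off the within-subject
  variance) degrade identification.
- Whole-data fingerprinting evaluates on the training segments; only the
  cross-validated and generalization variants measure out-of-sample
  performance.
- The Gibbs sampler runs one chain; split-half R-hat can miss multimodality
  that multiple dispersed chains would reveal.
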