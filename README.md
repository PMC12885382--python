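# sleepprint

Individual "fingerprinting" from pediatric sleep-EEG power spectra with a
latent-noise Bayesian reduced-rank regression (BRRR).

Children's sleep EEG carries stable, individual spectral idiosyncrasies on
top of strong maturational trends: total power rises and then falls with
age, oscillatory peaks (alpha, sleep spindles) emerge and drift, and muscle
artifacts contaminate light sleep. `sleepprint` asks whether a subject can
be re-identified from a different segment of their own recording — and how
identifiability relates to age, sex, cap size and artifact load.  It is
aimed at researchers working with multi-subject clinical EEG cohorts who
want a tested, reproducible reference implementation of spectral
fingerprinting, and it ships a synthetic-cohort generator so the entire
analysis can be exercised (and its statistics calibrated) without access to
clinical data.

## The model

Observations are relative bandpowers: per subject, six 60-s epochs (two N1,
four N2) are Welch-transformed (Hamming window, nfft = 1024 at 250 Hz) and
reduced to 13 log-widening bands x 19 channels = 247 features per epoch,
each channel's 13 values summing to one.  Stacking epochs gives the
response **Y** (n x s) and a one-hot subject membership design **X** (n x p).
The latent-noise BRRR is

    Y = (X Psi + Omega) Gamma + E

with subject coefficients Psi (p x k), latent noise Omega (n x k) entering
through the *same* projection Gamma (k x s) as the signal, and independent
Gaussian residuals E.  Theta = Psi Gamma is the rank-k regression
coefficient matrix; a multiplicative gamma-process shrinkage prior on
Gamma's rows enforces k << p, s.  Inference is Gibbs sampling (1000
iterations, 500 burn-in by default), initialized from Fisher's linear
discriminant.  Fit quality is the proportion of total variance explained,

    PTVE = tr(Cov(X Psi Gamma)) / tr(Cov(Y)),

which excludes the latent noise.  Fingerprinting projects each epoch into
the latent space via `Y pinv(Gamma)` and matches subjects by minimum L1
distance (the correlation baseline instead matches full 247-dim feature
vectors by maximum Pearson correlation).  Per-subject distinctness is the
differentiability score

    D_self(i) = -( d(a_i, b_i) - mu_{d\i} ) / sigma_{d\i},

the Z-score of the self pair against subject i's pairs with everyone else.
Group-level statistics include cluster-level permutation tests on PSDs,
Mantel tests between dissimilarity matrices, and OLS regressions of
differentiability on age, sex, cap size and an EMG log-ratio noise
covariate.

## Worked example

```bash
sleepprint demo --seed 1 --out demo_out
```

simulates a 30-subject cohort (ages drawn from a right-skewed distribution,
majority under 5 y), extracts features, fits a scaled-down model (K = 10,
600 Gibbs iterations) and prints:

```
sleepprint run summary
======================
package 0.1.0  config 6447e98600b3fdaf  seed 1
cohort: 30 subjects, median age 3.8 y, 70% under 5 y
brrr: success rate 1.00, mean differentiability 3.68, PTVE 0.86
correlation: success rate 1.00, mean differentiability 1.53
10-fold CV: BRRR 1.00 (corr 1.00), train PTVE 0.86
MCMC: max R-hat 1.044, min bulk ESS 47, 4 flagged entries
Mantel BRRR vs correlation: r = 0.66, p = 0.001
```

Reading this: both methods identify every subject from the paired N2
segments (success rate 1.00 in-sample and in 10-fold cross-validation —
the synthetic cohort is deliberately high-signal); the BRRR latent space
separates individuals more sharply than raw feature correlation (mean
differentiability 3.68 vs 1.53); the rank-10 mean explains 86% of the
feature variance; and the two methods largely agree on which subjects
resemble each other (Mantel r = 0.66).  The flagged ESS entries reflect the
demo's shortened chain; the default settings (K = 30, 1000 iterations) are
used outside the demo.  The library surface (`sleepprint.synthdata`,
`features`, `brrr`, `fingerprint`, `groupstats`) exposes every step
individually; `sleepprint run --config my.yaml` drives the same pipeline
from a YAML file (`sleepprint write-config default.yaml` to start).

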