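# Methods

## The problem

Conventional functional-connectivity measures summarise the coupling
between two brain signals at a single time scale. Neural signals, however,
are scale-free: their fluctuations and their couplings carry long-range
temporal correlation, and the strength of that coupling is itself a
dynamic quantity. `fractalconn` estimates *dynamic fractal connectivity*:
a time-resolved, scale-resolved coupling coefficient between every pair of
EEG channels, together with a time-resolved univariate scaling exponent
per channel, and the machinery to ask which of those couplings separate
two groups of subjects (here: young vs elderly) and how they relate to
cognitive performance.

## Detrended cross-correlation and the coupling coefficient

For two series $x_t, y_t$ of length $T$, form the integrated profiles
$X_t = \sum_{i\le t} x_i$, $Y_t = \sum_{i\le t} y_i$. At scale $s$ the
profiles are divided into the $K_s = T - s + 1$ maximally overlapping
sub-windows of length $s$; in each sub-window both profiles are detrended
by their own OLS line and the residual cross-covariance is computed with
divisor $s-1$. Averaging over sub-windows with divisor $K_s - 1$ gives the
bivariate scaling function $F^2_{xy}(s)$; with $y = x$ this is the DFA
scaling function $F^2_{xx}(s)$. The detrended cross-correlation
coefficient

$$\mathrm{DCCC}(s) = \frac{F^2_{xy}(s)}{\sqrt{F^2_{xx}(s)\,F^2_{yy}(s)}}$$

is bounded in $[-1, 1]$ (Cauchy–Schwarz over the shared sub-window
decomposition) and plays the role of a scale-dependent correlation
coefficient. Negative values are meaningful (anticorrelated couplings) and
are retained throughout.

The univariate scaling exponent per analysis window is the OLS slope of
$\log F_{xx}(s)$ on $\log s$ across the scale set — equivalently half the
slope on $\log F^2$; we regress $\log F$ and document that choice since
the slope convention halves between the two. The temporal variance of the
windowed exponent serves as a rough proxy for the degree of
multifractality (time-varying scaling).

### Sliding-window protocol and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| scales $s$ | 8, 16, 32, 64, 128 | samples | dyadic; at 256 Hz, $f \approx f_s/s$ spans 2–32 Hz |
| analysis window | 1024 | samples | resolves the largest scale with $\ge 8$ sub-window spans |
| step | 128 | samples | 0.5 s; 87.5 % overlap |
| detrending order | 1 (linear) | — | standard DCCA practice |
| epoch | 72 | s | 18 432 samples → 137 analysis windows |

A 72-s epoch at 256 Hz with this plan yields exactly 137 windows, and 14
channels × 91 pairs × 5 scales × 137 windows = 62 335 dynamic features
per subject. The window length and step are specified in **samples**; the
seconds labels above are the 256-Hz equivalents.

Each analysis window is mean-centred per channel before integration
(switchable via `center=`): without centring, the profile's deterministic
drift dominates the fluctuation functions and windowed estimates are not
comparable. Profiles are additionally detrended by their global OLS line
before the sliding computation — per-sub-window linear detrending is
exactly invariant to this, and it avoids catastrophic cancellation in the
sliding cumulative sums (verified against a brute-force per-sub-window
oracle to better than 1e-10 relative error).

Constant (zero-variance) channels produce NaN coefficients, flagged and
logged, never silent zeros; windows containing flagged values are dropped
when feature matrices are assembled, with the count logged.

## Preprocessing

Raw recordings pass through a 4th-order zero-phase Butterworth band-pass
(0.5–45 Hz by default; applied forward and backward, so the effective
magnitude response is the squared Butterworth gain), common-average
re-referencing, and trimming to a fixed-length epoch. An explicit offset
(or a seeded random-offset helper) replaces interactive epoch selection;
ICA-based artifact rejection is a human-in-the-loop step and is out of
scope — externally cleaned data passes through unchanged.

## Group decoding: SVM-RFE with correlation-bias reduction

The feature matrix has one row per (subject, window) and one column per
(pair, scale). Decoding uses linear SVMs throughout (features z-scored
with training-fold statistics; weight magnitudes are otherwise
scale-confounded).

**Folds.** Extensive leave-one-subject-out cross-validation: one fold per
(young, elderly) subject pairing — 24 × 19 = 456 folds for the full
design — with all of a subject's windows kept on one side, so decoding
reflects group structure rather than subject identity.

**Ranking.** Per fold, recursive feature elimination: train, score
features by squared weight, eliminate the lowest 50 % of the active set,
then *correlation-bias reduction*: within the just-eliminated batch, find
clusters of features with pairwise |Pearson r| > 0.9 (connected
components on the training data) and restore each cluster's
highest-importance member, so that mutually redundant features cannot
bury one another. Once ≤ 20 features remain they are removed one at a
time, yielding a strict elimination order. Fold rankings are averaged;
ties break by mean importance, then feature index.

**Subset.** Features are added back in average-rank order; the prefix
maximising mean cross-validated sample-wise accuracy (smallest size on
ties) is the chosen set. Performance is reported as sample-wise and
majority-vote subject-wise accuracy (vote ties broken by summed decision
values; odd window counts cannot tie) with Cohen's kappa, against the
chance level from the exact binomial inverse CDF: for a 274-window test
set (2 subjects × 137 windows) at α = 10⁻⁴ the threshold is 61.31 %. The
exact CDF is used deliberately; a normal approximation lands on a
different threshold.

The regularization parameter C is searched over {10⁻², …, 10²} in the CLI
and drivers; no class weighting is applied (training sets are
near-balanced).

## Statistics

* Two-group comparisons gate on normality: Lilliefors (KS with estimated
  mean/sd, as implemented in statsmodels) on each sample at α = 0.05;
  both normal → two-sided Welch t (robust to unequal variances), else
  two-sided Mann-Whitney U.
* Benjamini-Hochberg step-up FDR for the per-channel DFA-exponent
  comparisons; post hoc comparisons on the RFE-chosen connections are
  reported **unadjusted** (a pre-selected set, described rather than
  discovered) — both behaviors are explicit flags.
* Brain-behavior: Spearman ρ (average-rank ties) between each chosen
  connection's summary statistics and each cognitive score, per group,
  unadjusted; p by the t approximation for n ≥ 10 and by exact
  permutation enumeration below that.
* The strength-variability relation: Pearson r between the absolute
  time-mean ⟨|DCCC(s)|⟩ and the temporal variance σ²_DCCC(s) across
  chosen connections, per group and pooled, with the OLS line. On
  cohorts with strong couplings this correlation is negative — stronger
  couplings fluctuate less.

## The synthetic cohort

No EEG or cognitive data ship with the package; a generator produces
cohorts with the statistical structure the analysis assumes, so every
stage can be validated against known ground truth.

* **Signals.** Each channel is unit-variance fractional Gaussian noise
  (circulant-embedding synthesis of the exact fGn autocovariance) with a
  group-mean Hurst exponent — 0.75 young vs 0.65 elderly by default, a
  broadband EEG scaling contrast of realistic magnitude and direction for
  healthy aging. fGn (stationary increments) rather than fBm, since the
  analysis integrates internally and EEG is treated as a noise-like
  signal.
* **Couplings.** A planted connection mixes a shared source into its
  second channel, `y ← r·x + sqrt(1-r²)·y`, preserving unit variance;
  the signed strength r is group-specific. Band-limiting the shared
  source targets the coupling at the detrending scales whose equivalent
  frequency f_s/s falls in the band.
* **Heterogeneity.** Group parameters are population means. Per subject:
  Hurst jitter (sd 0.02), per-connection coupling jitter (sd 0.1), and a
  global coupling gain (sd 0.35) scaling all connections together —
  individuals differ in overall connectivity strength, not only
  connection by connection.
* **Dynamics.** Coupling strength is modulated by a slow (~4 s
  correlation time), positive, mean-one envelope shared by all
  connections (cv 1.0), so sliding-window estimates fluctuate the way
  dynamic functional connectivity does.
* **Global-mode episodes.** A few brief episodes (3 × 2 s by default)
  mix a common broadband source into *all* channels, as uncorrected
  artifacts or global synchronization would; the affected windows carry
  little group information and put a floor under decoding error.
* **Scores.** Cognitive scores are noisy linear functions of named
  connectivity summaries — monotone brain-behavior relations with known
  sign, plus pure-noise scores for calibration checks.

All randomness flows from one master seed through `SeedSequence`
spawning; cohorts are bit-reproducible.

What the generator does **not** emulate: volume conduction, oscillatory
(alpha/beta) spectral peaks, non-Gaussian amplitudes, electrode noise.
Passing recovery tests on these cohorts therefore validates the
estimators and the selection machinery, not the physiological
interpretation of any real-data result.

### The reduced validation cohort

End-to-end validation uses a 6+6-subject, 6-channel cohort with 30
analysis windows and scale set {8, 32, 128}, carrying three planted
discriminative (pair, scale) features at a group contrast of Δρ = 0.5:
two high-frequency couplings (16–64 Hz, loading scale 8) and one mid-band
coupling (6–12 Hz, loading scale 32). The largest scale (128) is not used
as a planted target: with 1024-sample analysis windows it averages only
~8 independent detrending spans, and its estimator is too noisy for a
single connection to carry a reliable planted effect at this cohort size.
On this design the full RFE + ELOO pipeline recovers all three planted
features in the large majority of seeds (≥ 8/10 is the acceptance bar;
18/20 observed across the first twenty seeds during design validation).

## Numerical and engineering choices

* The sliding computation is fully vectorized: per analysis window, one
  pass of cumulative sums yields every pairwise residual covariance at
  every scale; the per-window cost is O(channels² × window length) per
  scale. Equivalence with the naive per-sub-window OLS implementation is
  property-tested at 1e-10 relative tolerance.
* Eq-level conventions (overlapping sub-windows, divisors s-1 and K_s-1)
  are kept exactly as stated above; using non-overlapping sub-windows
  changes constants but not exponents.
* SVMs are `sklearn.svm.SVC(kernel="linear")` — deterministic for fixed
  input; the whole pipeline is bit-reproducible for a fixed seed.
* Tensors persist to HDF5 (with pair table, scale table, window starts,
  labels); tables to CSV; metrics to JSON. Channel-pair order is
  row-major over the lower-triangle index pairs (i < j) and persisted.

## Problem sizes used by the test suite and drivers

The full 24+19 study design (456 folds × 62 335 features) is exercised
for its closed-form quantities; statistical validation runs on the
reduced cohort and on 18 432-sample two-channel recordings, sizes at
which the full pipeline completes in seconds to a couple of minutes on a
single core. The `analysis/` drivers default to an 8-per-group subsample
for the decoding stage for the same reason; `--max-subjects-per-group 24`
runs the full design.

## Known limitations

* The add-back subset rule (argmax accuracy, smallest k on ties) makes
  the chosen-set *size* unstable between cohort realizations even when
  the top-ranked features are stable; this mirrors the procedure it
  reproduces, which is descriptive rather than a deployable classifier.
* The ranking is computed with all folds' training data; as with the
  original procedure, it is not a nested, deployment-grade CV and the
  reported accuracies should be read accordingly.
* Lilliefors-gated test routing is itself a pre-test procedure whose
  compound error rate is not controlled; it is reproduced as specified.
* DFA/DCCA estimates at scales approaching window/4 are noisy; exponents
  from 5 dyadic scales are rough local estimates, adequate for contrasts
  but not for precise H estimation.
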