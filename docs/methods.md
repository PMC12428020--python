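# Methods

This note records the modelling and numerical choices behind the
package, in the order the pipeline runs.

## Synthetic cohort model

Each channel of a synthetic recording is a sum of independent
band-limited Gaussian processes, one per canonical EEG band: white
noise band-passed with a 4th-order Butterworth filter applied
forward-backward (zero phase), normalised to unit variance, and scaled
by the square root of the profile's relative *power* gain for that
band. A 1/f^α pink background (α = 1 by default) is added with power
equal to 10 % of the summed band gains. Channels are generated
independently except for a per-band shared source mixed in with
amplitude weight √0.2, which creates realistic inter-channel
correlation without committing to any scalp topography. Per-subject
variability is a multiplicative gain jitter per band,
`max(0.05, 1 + cv·z)` with `z ~ N(0,1)` (cv = 0.1 by default); the
floor prevents non-physical negative gains.

Filtered-noise band mixing was chosen over AR or coupled-oscillator
models deliberately: its ground truth *is* the band-power vector the
downstream features estimate, so parameter recovery is a closed-loop
test of the whole pipeline rather than a proxy.

Default class profiles encode the qualitative dementia signature of
spectral slowing:

| class | δ | θ | α | β | γ |
|-------|----|----|----|----|----|
| HC (alpha-dominant) | 0.15 | 0.15 | 0.40 | 0.20 | 0.10 |
| AD (slow-shifted)   | 0.30 | 0.30 | 0.15 | 0.15 | 0.10 |
| FTD | HC profile everywhere except frontal channels (Fp1, Fp2, F7, F3, Fz, F4, F8), which carry the AD/HC midpoint |

There are no published quantitative per-class spectral profiles to
copy; these magnitudes are stand-ins chosen to be plainly separable,
and they are ordinary config values (`ClassProfile`) rather than
constants. A `separation` knob interpolates the non-HC profiles
toward HC (0 = no class structure); `null_cohort_config()` gives all
three classes one identical profile with zero jitter, for
chance-level calibration.

What the generator does **not** emulate: eye-blink/EMG artifacts,
within-recording nonstationarity, volume-conduction topography, and
subject-level covariates. Tests passing on synthetic cohorts
therefore demonstrate the correctness of the pipeline's mechanics and
its ability to recover band-power class structure — not clinical
performance on real EEG.

## Preprocessing

Epochs are 0-based half-open windows `[start, start + L)` with
`L = round(30 s · fs)` and stride `round(15 s · fs)`; partial trailing
windows are discarded so every feature row comes from a full-length
epoch. Recordings shorter than one epoch are skipped with a warning,
not an error. The 0.5–45 Hz Butterworth hygiene filter (order 4,
forward-backward) is applied by default but can be disabled for
already-clean input.

## Spectral estimation

Welch PSD with Hamming taper, 75 % overlap, and 2 s segments
(1000 samples at 500 Hz). The segment length is the one free
parameter the analysis convention leaves open; 2 s gives 0.5 Hz
resolution, so the narrowest band (δ, 0.5–4 Hz) contains 7 bins.
One-sided density scaling with taper power correction is used, so the
integral of the PSD equals the signal's mean square (Parseval).

Band power is the **mean** PSD density over a band's bins (the
`(1/N) Σ X_i` reading), with an `integral` mode available; band edges
are half-open `[low, high)` and the topmost band (γ) closes at 45 Hz,
so the shared edges 4/8/13/25 Hz are never double-counted.

Band ratios carry an orientation switch. The reference feature tables
this analysis follows print the "theta–alpha band power ratio" with
the *alpha/theta* arithmetic (and likewise delta–theta as
theta/delta), so `ratio_orientation="inverse"`
(second-named/first-named band) is the default; `"named"` gives the
literal reading. 0/0 ratios propagate as missing; x/0 as +inf, also
treated as missing downstream.

## Time-domain moments

Skewness and kurtosis default to a hybrid convention common in
clinical EEG feature tables — population SD combined with an N−1
normaliser: `KU = Σ(x−x̄)⁴ / ((N−1)·SD⁴)`
(`moment_convention="literal"`). Under this convention the kurtosis
of a normal sample converges to `3N/(N−1)`, not 3;
`moment_convention="standard"` switches to the population moment
ratios. Constant signals yield missing SK/KU; epochs with any missing
feature are dropped with a logged count rather than imputed.

## Split and selection

Systematic sampling: within each class, row i (1-based, stored order)
is a test row iff `ceil(i·q) > ceil((i−1)·q)`, q = 0.3, giving
per-class test counts of `ceil(n·q)` (e.g. 1888 → 567, 1563 → 469)
and an evenly interleaved pattern. A small epsilon (1e−9) guards the
ceiling against float noise at exact integer multiples.

Labels are coded 1/2/3 in the order (AD, HC, FTD) — the concatenation
order of the emulated cohort — and both correlation methods are
computed against those codes; the order is a logged config item
because the coefficients depend on it. Spearman is implemented as
Pearson on midranks (the operative definition under the heavy ties of
integer labels); Pearson is the standard product-moment coefficient.
Correlations use training rows only; the test-label-permutation
invariance of the report is asserted in the tests.

RTH is the mean of |r| over all 342 features, with missing
coefficients contributing zero and never being selected; selection is
strict (`|r| > RTH`), ordered by descending |r| with ties broken by
ascending flat index.

## Classifiers and optimisation

The "quadratic" SVM kernel is the standard degree-2 polynomial
`(u·v/s² + 1)²`; `s = "auto"` means `√(n_features)` after
z-scoring, so `gamma = 1/n_features` in the underlying libsvm
parameterisation. Multiclass is one-vs-one voting; per-class scores
for ROC are the aggregated signed distances. Standardisation
statistics always come from the training side (and are refit inside
every CV fold).

k-NN uses cosine distance `d = 1 − cos(u,v)` and squared-inverse
weights `1/d²`; distances are clipped below at 1e−12, which realises
the exact-match limit (a zero-distance neighbour's weight dominates
every finite weight, and ties among several exact matches reduce to
their majority vote). Prediction ties break by the configured class
order.

Bayesian optimisation runs on the unit interval (log-scaled for C,
rounded for k): 5 Halton initial points, then 25 iterations, each
fitting a Matérn-5/2 GP (observation jitter 1e−6, constant-mean via
y-normalisation, marginal-likelihood hyperparameter fit) and taking
the expected-improvement argmax over a fresh 1000-point random grid.
EI uses the closed form `(μ−f*)Φ(z) + σφ(z)` with the σ = 0
degenerate case `max(0, μ−f*)`. The objective is mean 5-fold
stratified CV accuracy on the training split (resubstitution is
available as `objective="resubstitution"`; the two can disagree, and
neither is asserted against any external table). Failed objective
evaluations (e.g. k larger than a fold) are logged and skipped.

## Evaluation

All per-class rates come from one-vs-rest reductions of the C×C
confusion matrix; reported single values are unweighted macro means
(consistent with the explicitly per-class BCR definition), with
undefined per-class values (empty denominators) excluded from the
macro mean and logged. Accuracy is in percent; everything else is a
fraction in [0, 1]. ROC curves are stored as (FPR, TPR) with
trapezoidal AUC; macro AUC is primary and a pooled micro AUC is also
reported.

## Pipeline and reproducibility

The default split is epoch-level, mirroring the reference protocol —
which means 50 %-overlapping epochs of one subject can land on both
sides of the split, an acknowledged leakage channel. The
`subject_wise` flag applies the same systematic pattern to whole
subjects instead; both modes are recorded in the run manifest. The
chance-level null-cohort check in the test suite uses the
subject-wise mode precisely because, with epoch-level splitting, a
null cohort measures overlap leakage rather than classifier
calibration; the strongly-separated recovery check keeps the default
epoch-level mode.

Every source of randomness derives from one master seed
(per-subject generator seeds, CV fold shuffles, BO candidate grids),
and reruns are byte-identical, which the tests assert. Problem sizes
used by the test suite and the acceptance script — cohorts of 4–20
subjects per class, 60–180 s recordings — were chosen as the smallest
sizes at which the statistical claims under test are stable.

## Known limitations

* The synthetic generator's realism caveats above: green tests do not
  imply clinical-grade performance on hospital EEG.
* EDF files can be read (via mne) but not written; the native on-disk
  format is a delimited text matrix with a JSON sidecar.
* BO is 1-D by design (one hyperparameter per classifier family);
  joint multi-parameter search is out of scope.
* No artifact removal (ASR/ICA) is implemented; input recordings are
  assumed clean apart from the hygiene band-pass.
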