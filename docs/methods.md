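# Methods

## Signal model of the synthetic generator

Each trial is 10 s of simultaneous EEG (30 channels, 200 Hz) and fNIRS ΔHbO
(36 channels, 10 Hz), 30 trials per class, the two classes standing for
left- vs right-hand motor imagery.

**EEG.** Channel traces are a sum of (i) 1/f-shaped broadband background
(spectral synthesis, amplitude ∝ f^−0.5 over 0.5 Hz–Nyquist, sd
`eeg_background_sd` = 10 µV by default) and (ii) a band-limited 8–30 Hz
process (random spectral phases) with rms `eeg_osc_rms` = 4 µV and ~15%
trial-to-trial amplitude jitter.  On informative channels the oscillation
amplitude of class 1 is multiplied by `1 − eeg_effect` — an event-related
desynchronization analogue.

**fNIRS.** Channel traces are a gamma-variate hemodynamic response
(shape 6, peak at 5 s, unit amplitude, 15% jitter) plus a <0.01 Hz drift
sinusoid (amplitude 0.3), a ~1 Hz cardiac sinusoid (amplitude 0.1, 5%
frequency jitter), and band-limited (<1.2 Hz) measurement noise
(`fnirs_noise_sd` = 0.45).  On informative channels the response amplitude
of class 1 is multiplied by `1 + fnirs_effect`.  Because the noise is
band-limited below 1.2 Hz, the spectrum above the cardiac line is empty by
construction — a property the tests verify.

Signals are emitted directly at the post-downsampling rates (200 / 10 Hz);
the resampling operation is exercised separately on synthetic high-rate
inputs rather than baked into every fixture.

**What the planted ground truth means.** An amplitude effect survives the
preprocessing chains only in specific statistics: after the 8–30 Hz
band-pass the EEG mean and slope are ~0 and skewness/kurtosis are
scale-invariant, so an ERD effect is expressed in the *peak*; after the
0.01 Hz high-pass the per-trial fNIRS mean is removed, leaving *slope* and
*peak*.  With 2 informative channels per modality the planted set is
therefore exactly 6 of the 330 fused features, and ranking all columns by
standardized mean difference confirms those six occupy ranks 1–6.

**Effect-size presets.**  The defaults put the per-feature Cohen's d of the
planted features at ≈1.2–1.9 (a pronounced but realistic single-subject
contrast).  `strong_effect_config()` (eeg_effect 0.7, fnirs_effect 1.5,
background sd 4 µV, fNIRS noise sd 0.20) raises it to d ≈ 3–5, the regime
in which a single planted feature nearly separates the classes.  These
values were fixed once from a pilot measurement of d and are not tuned per
experiment.

**What the generator does not model:** EOG contamination (the regression
stage is exercised with injected references in tests), ΔHbR, multi-class
tasks, inter-subject variability, non-stationarity within a session, and
channel correlations beyond the common average reference.  Consequently,
passing tests show the machinery is correct and well-calibrated on
needle-in-haystack planted signal; they do not certify performance on real
recordings, whose informative structure is distributed and correlated.

## Preprocessing

All filters are Butterworth in second-order-section form, applied
forward–backward (zero phase) with even-reflection padding of the whole
epoch.  Zero-phase filtering was chosen because the analysis is offline and
trial-wise, and phase distortion would corrupt the slope features; it
doubles the effective order, so the −3 dB checks use the squared design
response.  Whole-epoch padding lets the 0.01 Hz high-pass behave sensibly
on 10 s epochs and keeps the operator linear and time-reversal symmetric.
Unspecified orders (fNIRS high-pass, EEG 0.5–50 Hz pre-filter) are set to 3
to match the stated third-order filters.  Epochs are filtered per trial
(continuous-recording filtering before epoching is out of scope).  EOG
removal is a least-squares regression of a 0.5–5 Hz-band reference out of
each channel — a deliberate simplification of hybrid ICA–regression
schemes; the residual is exactly orthogonal to the reference.

## Features, normalization, fusion

Five statistics per channel per trial, in fixed order (mean, slope, peak,
skewness, kurtosis).  Skewness and kurtosis are the population
(biased) moment estimators, kurtosis non-excess (normal → 3); zero-variance
windows raise an error rather than emitting NaN.  Slope is the OLS
coefficient against time in seconds.  Min–max normalization is computed per
column on training rows only and applied to all rows (held-out rows may
leave [0, 1]); a flag reproduces the leaky fit-on-everything variant for
comparison, but it is never the default.  Fusion concatenates the fNIRS
block before the EEG block (180 + 150 = 330 columns) with per-column
provenance preserved.

## Whale optimization

Conventional WOA follows the canonical three-rule scheme with scalar
per-whale coefficients, generational updates, an elitist incumbent, clip
repair at the box bounds, and spiral shape constant c = 1.  The ρ draw
precedes the A draw; branch order is ρ, then |A|.

E-WOA adds: a pool of k = 2N candidates warm-started from the initial
population; per iteration one pool slot (chosen uniformly) is overwritten
by a crossover that takes each coordinate from a sample near the incumbent
best (uniform box of half-width 0.1·(ub−lb)) or from the current worst
whale, according to a random bit vector; a randomly chosen 20% of whales
migrate to `X_rnd − X_brnd`; the remaining whales follow the ρ/|A| switch
with preferential selection (`X_i + A(C·P₁ − P₂)`, distinct pool members)
in place of random search and pool-enriched encircling
(`X_best − A|C·X_best − P₃|`) in place of conventional encircling.  The
pool is refreshed before movement.

**Binary variant.** Positions live in [0, 1]^D; a transfer rule maps them
to masks.  Two transfers are provided: deterministic thresholding at 0.5
(`identity`) and a steep logistic (`sigmoid`, slope 10) with stochastic
rounding.  The sigmoid is the default for feature selection: with a
deterministic threshold, whales that cluster on the incumbent re-evaluate
the identical mask, and measured distinct-mask coverage falls below that of
random search; stochastic rounding turns those duplicate evaluations into
local Hamming exploration and raises the exhaustive-oracle hit rate on an
8-feature benchmark from 8/20 to 19/20 seeds.  Empty masks are repaired to
the single largest coordinate.  The best mask *ever evaluated* is returned,
not the final population best.

**A known asymmetry on centred benchmarks.**  On the origin-centred sphere,
scalar-coefficient WOA encircling with `X_i ≈ X_best` reduces to
multiplying the whole position vector by `(1 − A|C − 1|)` — a pure
contraction toward the origin, which happens to be the optimum.  E-WOA's
enriched encircling distances are anchored to pool members rather than the
whale's own position, so it cannot inherit this artifact, and its final
sphere fitness at a 500-evaluation budget is orders of magnitude above
conventional WOA's (while on a shifted sphere the two are comparable, and
on feature-selection benchmarks E-WOA is clearly stronger: oracle hit rate
19/20 vs 5/20).  Sphere benchmarks centred at the origin should therefore
not be read as evidence against E-WOA's selection quality.

## Wrapper cost and evaluation protocol

`fitness = α(1 − acc_cv/100) + (1 − α)(n_selected/D)` with α = 0.99,
acc_cv from stratified 5-fold CV of a linear SVM (C = 1) on the masked
training columns.  Folds are drawn once per run seed and reused, making the
cost a pure function of the mask; identical masks are served from a cache.
The protocol runs 10 repetitions of a stratified 80/20 split (fresh split
per run by default; a fixed-split mode re-seeds only the optimizer);
normalization, selection and training see only the 80% — held-out rows
enter a single final accuracy call.  Methods are compared with Welch's
t-test on per-run accuracies (pooled-variance optional); two identical
constant samples are reported as t = 0, p = 1.

**Honest limits of wrapper selection at this sample size.**  With 48
training trials and 330 candidate features, roughly 500 masks are scored
per selection run against one fixed fold assignment, so the maximizer of
CV accuracy is optimistically biased (winner's curse).  Two consequences,
both visible in the planted experiments: (i) the selected mask is a
*minimal sufficient* subset, not the complete planted set — at strong
contrast one or two planted features already reach 100% CV accuracy
(accuracy resolution is 1/48 ≈ 2.1%), and the 1% count term then prunes the
redundant rest, so planted-feature recall saturates near the minimal-subset
fraction; (ii) at moderate contrast, spurious noise subsets can outscore
the planted signal on the fixed folds, and the selected masks generalize no
better than the full feature set.  Repeated-CV scoring (averaging several
fold assignments) was evaluated as a mitigation; it did not change (i) and
slowed every experiment threefold, so the single fixed assignment — which
keeps the cost deterministic and the exhaustive-oracle comparison exact —
was retained.

## Numerical and reproducibility choices

One master seed feeds a SeedSequence tree from which every stage
(simulation, per-run splits, optimizer, transfer rounding) derives its own
generator, so the full pipeline is bit-reproducible; reports are persisted
as TSV and compared byte-for-byte in tests (at a reduced problem size —
12 trials/class, 3 runs, 10 iterations — since reproducibility does not
depend on scale).  Degenerate inputs fail loudly: single-channel CAR,
cutoffs at Nyquist, zero-variance windows, empty masks, pool capacity
below 2, unknown config keys.  A zero-variance EOG reference and constant
training columns degrade gracefully with logged warnings, as mid-pipeline
aborts would be worse than a no-op there.

Problem sizes used by the shipped experiments: the planted and null
experiments use the full default geometry (60 trials, 330 features,
10 runs); the sphere and oracle benchmarks use 20 seeds at the protocol's
10 whales × 50 iterations.
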