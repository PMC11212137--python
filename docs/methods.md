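# Methods

## Signal model

A recording is modeled as an open-pore current baseline I₀ (default 250 pA
at 110 mV in 4 M KCl) carrying white Gaussian noise, interrupted by
rectangular blockade events and passed through the acquisition low-pass
filter. Each event population (a peptide conformation/entry mode) is
parameterized by a normalized blockade depth g ~ Normal(m, s) truncated to
(0, 1) — the event level is I₀(1 − g) — an exponential dwell-time
distribution with mean τ, and a Poisson arrival rate λ. Populations
superpose; an arrival that would overlap an existing event (within a guard
gap of about four filter rise times) is re-drawn at a new arrival time, so
the realized process is a hard-core Poisson process. Event onsets fall on
sample boundaries; sub-sample jitter is not modeled.

The acquisition chain is 250 kHz sampling with a 5 kHz low-pass. The filter
family of the original acquisition software is not specified beyond its
cutoff, so the package uses a Gaussian filter whose −3 dB point sits at the
cutoff: time-domain sigma σ_t = f_s·√(ln 2)/(2π f_c) ≈ 6.6 samples at
250 kHz/5 kHz (`gaussian_lowpass`, swappable by filtering an unfiltered
simulation externally). A Gaussian filter attenuates white-noise sd by
(2 σ_t √π)^(−1/2) ≈ 0.206 at these settings (`noise_attenuation`).

### Noise defaults

Noise amplitudes are injected *before* the filter (as in a real amplifier
chain), so the observable trace noise is the injected sd times the
attenuation factor. Defaults:

* baseline white noise 9 pA → ≈1.86 pA on the filtered trace, matching the
  ≈1.8 pA open-pore sd of typical recordings, and putting the 7σ detection
  threshold (≈13 pA) far below the shallowest population depth
  (0.39 × 250 ≈ 98 pA);
* intra-event white noise 15 pA → ≈3.1 pA filtered, safely above the 1 pA
  bumping-rejection floor so genuine events survive the filters.

Both are per-population/config tunables in pA.

### Study conditions

`paper_conditions()` returns the population sets used throughout:

| condition | populations (depth of I₀ / dwell τ µs / rate Hz) |
|---|---|
| l native | Type I 0.72/440, Type IIa 0.43/820, Type IIb 0.48/820; total 19.1 Hz |
| d native | Type I 0.71/390, Type IIa 0.39/1140, Type IIb 0.43/1140; total 28.1 Hz |
| l + TCEP | single 0.53/500; 153.3 Hz |
| d + TCEP | single 0.49/500; 107.2 Hz |
| equimolar mix | Type IIa of each peptide at its native share |

Depths, dwell constants (native) and total rates are the reported
single-peptide values. Three quantities are not reported and are package
choices: the event share among Type I/IIa/IIb within a condition (15/55/30%,
making Type IIa dominant as observed), the population depth sds (0.015 for
Type II and TCEP, 0.02 for Type I — consistent with 0.005-binned histograms
that resolve the 0.39/0.43 pair), and the TCEP dwell constant (500 µs).

## Detection and featurization

I₀ and σ are estimated by iterative 3σ clipping around the dominant level,
starting from the median/MAD; a trace whose clipped retention falls below
50% or whose clipped kurtosis is below 2 (a two-level trace clipped around
its midpoint) is rejected as having no dominant level. An event spans the
maximal run of samples below I₀ − kσ (k = 7 by default); runs touching the
trace ends are discarded. Dwell is span × sampling interval; with the
Gaussian filter the threshold crossings sit on the edge ramps, so detected
dwell exceeds true dwell by a constant ≈2 × 1.2 σ_t (≈64 µs at the default
settings) — immaterial for exponential decay constants, and bounded by the
ledger-based tests.

In-event statistics (I_b, I_bmax, I_bmin, I_bs) are computed over a core
that trims up to ⌈3.6 σ_t⌉ samples from each edge (never below 8 central
samples), excluding the filter's rise/fall ramps; without this the mean
blockade of an 800 µs event would be biased shallow by several percent.
Events shorter than two samples get NaN I_bs and a `short` flag. The
standard filters remove events with dwell < 200 µs (inclusive at the
floor), I_bs < 1 pA, or ΔI_b/I₀ < 0.2; removal counts are logged per
criterion and conserved against the input count.

Known bias: over a short correlated-noise core the sample sd underestimates
the process sd, so a fraction of genuinely short (≲300 µs) events fails the
1 pA floor. This depletes the head of the dwell histogram but not its tail.

## Fits

* Blockade histograms: 0.005 bins over [0, 1]; Gaussian or bi-Gaussian
  least squares inside a population window with Poisson (√count) weights.
  Initial means come from the histogram mode (Gaussian) or the two most
  separated local maxima (bi-Gaussian); mean bounds extend 15% of the
  window width beyond it because a window-truncated peak's mean may sit
  just outside the visible range. Each fit runs 3× from starts perturbed
  ±20%; repeats trapped in a clearly worse local minimum (weighted SSE
  > 1.5× the best) are treated as non-converged; reported value/uncertainty
  are the mean/sd over converged repeats. Bi-Gaussian components are
  ordered by mean; components closer than one bin or than twice the
  narrower width are unresolved and are refit as a single Gaussian.
* Dwell times: logarithmic bins (30/decade); a single exponential is
  fitted to the count density of bins from the density mode (at or above
  the 200 µs floor) to the 99th dwell percentile, so the estimate is the
  tail decay constant, robust to the short-event depletion above and to
  the left truncation. A truncated-exponential MLE (`dwell_tau_mle`,
  mean excess over the floor) is provided as a cross-check.
* Event frequency: interevent times between consecutive detected event
  starts, 2 ms bins, single-exponential fit excluding the first bin (dead
  time); rate = 1/τ. Global frequency uses all detected events — applying
  the dwell filter first would thin the process and bias the rate. At high
  duty cycle the hard-core constraint raises the conditional intensity, so
  the fitted rate exceeds the nominal arrival rate by roughly 1/(1 − duty)
  (≈10% for the TCEP conditions, <2% at ≈19 Hz); the same dead-time effect
  exists in real recordings.

## Classification

The five parameters (T_t, ΔI_bmin, ΔI_bmax, ΔI_b, I_bs) are standardized
with the reference (d-peptide) dataset's means and sds, and the reference
correlation matrix is eigendecomposed; PC1/PC2 are the two leading
eigenvectors. Every dataset — including the reference itself, the second
peptide and mixtures — is standardized with the *reference* statistics and
projected through the same components, which is what makes "using the
correlation matrix calculated from the reference" meaningful. Sign
conventions remove the eigenvector ambiguity: PC1 loads non-negatively on
ΔI_b, and PC2 is oriented so the reference's main PC2 peak (median proxy)
is negative.

Each peptide's PC2 population is summarized by a Gaussian fitted inside
mode ± 2 robust sd (excluding the shoulder attributed to the open
conformation); a distribution with two comparable, well-separated peaks is
rejected with advice to fit per population. The band is [μ − 3σ, μ + 3σ],
closed at the edges.

Monte Carlo rule: an event outside both bands stays unlabeled; inside
exactly one band it takes that label; inside both it draws its label with
probability f_c(x)/(f_D(x) + f_L(x)) — the Gaussian densities at its PC2
value, equal class priors (the mixture composition is the unknown being
estimated). `expected_mc_recall` integrates this rule numerically and is
used as the test oracle. With the reported band parameters
(μ_D = −0.039, σ_D = 0.043; μ_L = 0.047, σ_L = 0.035) the rule's analytic
per-class recall is 80.6% with ≈19% false positives; pure-Gaussian PC2
populations put >99.8% of each class inside the band union, so any
band-respecting rule labels nearly every event and per-class recall plus
cross-labeling must sum to ≈100%. Reported recognition rates lower than
that (with a few percent unlabeled) therefore reflect non-Gaussian
structure of real PC2 distributions — the conformational shoulders — which
the Gaussian band simulation deliberately does not include; the package's
simulated recognition rates sit at the analytic value, not below it.

Confusion matrices count true class × predicted label over {D, L,
unlabeled}; per-class success divides correct labels by all true-class
events, the false-positive rate of a class divides the other class's events
labeled as it by the other class's total, and overall success divides all
correct labels by all evaluated events. Mixture ratios are
L-count/D-count with a Wilson binomial interval on the labeled fraction
transformed to the ratio scale; with overlapping bands, misclassification
compresses extreme ratios toward 1, so calibrated composition estimates
require well-separated bands or a misclassification correction (out of
scope). The logistic-regression baseline (scikit-learn, PC1/PC2 features,
20% stratified training split) makes hard decisions and cannot abstain;
with strongly overlapping distributions it is reported only for comparison.

## Simulated-data scope

The generator reproduces the statistical structure the analysis relies on —
baseline noise scale, event depth/dwell/rate distributions, filter
response — and supports every recovery test via its ground-truth ledger. It
does not emulate baseline drift, 1/f or interference noise, capacitive
spikes, multi-level events, or the non-Gaussian PC2 shoulders of real
conformational ensembles. Passing tests therefore demonstrate the
correctness of the analysis chain under the stated model, not performance
on arbitrary experimental data.

## Problem sizes and determinism

End-to-end checks simulate 20–180 s of trace per condition (2100–3000 true
events, ≥1700 surviving the filters, matching the per-experiment event
floor); band/classification checks use 4000 PC2 draws per class. A single
integer seed drives each simulation (one `numpy` Generator per call), and
orchestrated runs derive one child seed per stage from the master seed via
`SeedSequence.spawn`.
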