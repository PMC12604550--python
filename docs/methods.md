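# Methods

This note documents the models, estimators, numerical choices, and
limitations behind `lfpspace`, in the order data flows through the
pipeline.

## Synthetic sessions

**Generative model.** A session is a sequence of epochs (default 10 s
at 1 kHz) whose state follows a three-state Markov chain over
{SWS, NULL, REM_AWAKE}. Within an epoch, each frequency band b carries
three zero-mean Gaussian components per channel i:

    x_i(t) = Σ_b [ σ_g,b · g_b(t) + σ_s,b · s_i,b(t) + σ_n,b · n_i,b(t) ]

where g is shared by all channels, the spatial field s has
inter-channel covariance exp(−d_ij/ℓ) (realized by multiplying channel
noise with a Cholesky factor of that covariance; diagonal jitter up to
1e−5 is added if the factorization fails), and n is independent per
channel. The expected inter-channel correlation is the closed form

    ρ*(d) = Σ_b (σ_g,b² + σ_s,b²·e^(−d/ℓ)) / Σ_b (σ_g,b² + σ_s,b² + σ_n,b²),

which the test suite verifies to within 0.02 on pooled estimates over
≥100 epochs.

**Band-limiting.** Components are synthesized directly in the frequency
domain: complex Gaussian spectra are shaped by the squared-magnitude
response |H(f)|² of a 4th-order Butterworth band-pass (the zero-phase
forward–backward gain) and inverted with one real FFT per epoch. This
is circularly stationary — epochs carry no filter start-up transients —
and the per-sample variance of each component is normalized exactly on
the discrete frequency grid. Time-domain sos filtering of sub-hertz
corners also suffers a large denormal slowdown that this avoids.

**Default regime.** Two bands: SO/delta 0.1–4 Hz and gamma 30–60 Hz.
Per state, the variance fractions (global a, spatial s, local 1−a−s)
and generative ℓ were solved so that the *fitted* exponential
parameters land in the physiological operating range — correlations
near 0.8 in the first 600 μm bin falling toward 0.5 at 4.2 mm over a
mixed session, with fitted λ ≈ 4 mm in SWS and ≈ 6.5 mm in REM/awake:

| state | band split (δ:γ) | a | s | ℓ (μm) | ℓ jitter CV |
|---|---|---|---|---|---|
| SWS | 0.80 : 0.20 | 0.325 | 0.651 | 2800 | 0.17 |
| NULL | 0.25 : 0.75 | 0.248 | 0.542 | 3650 | 0.19 |
| REM_AWAKE | 0.08 : 0.92 | 0.170 | 0.434 | 4500 | 0.21 |

Band weights are variance fractions, but band *power* downstream is a
mean PSD (per Hz); since the gamma band (30 Hz wide) is ~7.7× wider
than SO/delta (3.9 Hz), the REM/awake gamma fraction must exceed ~0.885
for gamma density to dominate. The splits above give delta:gamma
density ratios of ~31 (SWS), ~2.6 (NULL), and ~0.67 (REM/awake), so
delta density dominates SWS and gamma density dominates REM/awake in
essentially every epoch.

The per-epoch lognormal jitter on ℓ (mean-preserving) reproduces the
within-state spread of fitted decay constants seen in chronic sleep
recordings, smallest in SWS. The NULL state is parameterized midway
between the other two, reflecting its transitional character. State
dwell times come from a transition matrix with stay probabilities 0.93
(SWS, REM/awake) and a brief NULL state, i.e. multi-minute bouts at
10 s epochs.

**Dropouts.** All-channel telemetry dropouts are injected at a Poisson
rate (default 0.02 Hz) with lognormal durations (median 0.3 s, σ = 1,
allowing multi-second tails). A burstiness parameter (default 0.3)
makes a fraction of dropouts start an exponential gap (mean 1 s) after
the previous one, so short inter-dropout intervals dominate. Dropout
samples are set to a constant and masked invalid.

**What the generator does not emulate:** 1/f spectral background,
sleep spindles, up/down-state dynamics, traveling waves, volume
conduction, or channel-specific noise levels. Tests passing on this
generator therefore demonstrate correctness of the estimators under
the assumed covariance/band-power structure, not robustness to every
property of real recordings.

## Preprocessing

Raw signals (e.g. 30 kHz) are low-passed with a zero-phase 3rd-order
Butterworth at 250 Hz and decimated by an integer factor to 1 kHz. The
forward–backward pass squares the magnitude response (a 300 Hz tone is
attenuated to ≈0.25, not ≈0.50); zero-phase filtering is used because
pairwise correlation is sensitive to cross-channel timing. No extra
anti-alias stage is needed since 250 Hz < the 500 Hz output Nyquist.
Channels are z-scored over mask-valid samples only; zero-variance
channels are excluded rather than interpolated. Epochs are
non-overlapping and contiguous; any epoch overlapping an invalid sample
is excluded from every downstream statistic (tests enforce this by
poisoning invalid samples with NaN). The virtual LFP is the mean of the
z-scored, non-excluded channels.

## Distance correlation functions

Per valid epoch, the Pearson matrix of the z-scored channels is Fisher
z-transformed and binned by inter-electrode distance. Bins are
half-open (lower, upper] with 600 μm width and are labeled by their
upper edge. Values with |r| ≥ 1 (railed or duplicate channels) are
clipped to ±(1 − 1e−7) before atanh and counted. Per source electrode,
z values are averaged within bins; source functions are pooled with
weights equal to their per-bin pair counts (edge electrodes see fewer
partners at a given distance). The analytic 95% CI for a z value is
z ± 1.96/√(n−3) with the *nominal* sample count n = epoch_s·fs; with
autocorrelated band-limited signals the effective n is smaller, so the
significance flag is anticonservative — a documented caveat of the
analytic approach. Narrowband functions band-pass the recording
(zero-phase, 4th order, applied via the squared-magnitude gain in the
frequency domain) before the identical binning pipeline.

## Decay models

Exponential and power-law fits are solved in the log domain by weighted
least squares (weights proportional to pair counts, not
variance-propagated — no error model is invented beyond the counts),
so they are linear regressions; A = exp(intercept), λ = −1/slope
(b = −slope on log d). Non-positive bin means cannot enter the log and
are dropped with a warning; fewer than two usable bins marks the epoch
failed. Slopes ≥ −1e−9 denote a flat profile: λ is capped at 1e6 μm
and A becomes the weighted geometric mean of z. The Gaussian model
A·exp(−d²/2σ²) + c is fit by weighted nonlinear least squares with
multi-start over σ ∈ {1, 2, 4} mm; the linear model by WLS. MSE is
always evaluated in the original z domain so models are comparable.
The optional low-count rule drops bins with fewer than 20% of the mean
count of the other bins before fitting. The (A, λ) scatter is
summarized by the standardized-major-axis Type-2 estimator
(slope = sign(r)·sd(λ)/sd(A)), chosen among Type-2 variants for scale
invariance, with a percentile bootstrap CI over case resamples
(default 1,000).

## Sleep staging

Band power per epoch is the mean one-sided multitaper PSD over
frequencies inside the band (inclusive edges), using 5 Slepian tapers
with time-bandwidth product 3 (exposed as parameters; at 10 s epochs
the 0.1 Hz lower delta edge is exactly resolvable). Features for
clustering are column-standardized log10 band powers — band power is
right-skewed, and the log makes the mixture components closer to
Gaussian. A full-covariance 3-component Gaussian mixture (fixed seed,
10 initializations) assigns epochs; components are mapped to states by
mean(delta) − mean(gamma) in feature space: largest → SWS, smallest →
REM/awake, middle → NULL, with ties broken by cluster index and
flagged.

## State coupling

The parameter ratio is λ/A (b/A for the power law) and the power ratio
is gamma/delta. Both are oriented to be *low* in SWS and *high* in
REM/awake — SWS couples high initial values and short decay constants
with delta-dominant power — which is the orientation under which their
correlation is positive; the implementation exposes the columns, so the
inverse orientation is a reciprocal away. d′ uses the pooled-SD form
|μ_a − μ_b| / √((s_a² + s_b²)/2) with n−1 variances. CVs are SD/mean
with percentile bootstrap CIs; bootstrap resampling is iid at the epoch
level. Densities are Gaussian KDEs with Silverman bandwidth on a shared
grid.

## Threshold classifier

The predictor smooths a per-epoch fit parameter with a centered moving
average (shrinking windows at the edges; width restricted to odd
values in {1, 3, 5, 7, 9}) and thresholds it. Candidate thresholds are
50 quantiles of the pooled training parameter augmented with midpoints
of adjacent quantiles, so a separable gap always contains a candidate;
the decision direction is learned per fold. The (width, threshold,
direction) triple minimizing mean misclassification error over the
training sessions is chosen per held-out session, with ties broken
toward smaller width, then smaller threshold. Significance is the rank
of the observed error in a uniform label-shuffle null (≥100 shuffles
required; default 1,000). Smoothing precedes thresholding.

## Problem sizes and determinism

The default synthetic study uses one 360-epoch (1 h) session for the
main analysis and three 80-epoch sessions for the classifier; the
closed-form recovery check pools 110 single-state epochs with ℓ jitter
disabled (the closed form assumes fixed ℓ). All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`, and
identical seeds give bit-identical sessions and byte-identical CSV
outputs. Signals are stored as float32 and synthesized in single
precision; estimator mathematics (correlations, fits, statistics) runs
in double precision.

## Known limitations

* The analytic CI and the significance flag ignore temporal
  autocorrelation (see above).
* Staging assumes exactly three clusters; recordings without one of
  the states will still be partitioned into three.
* The exponential/power-law fits require strictly positive bin means;
  profiles crossing zero (possible in narrow high-frequency bands)
  lose those bins.
* Generator realism is limited to the component structure described
  above; absolute amplitudes are calibrated only to correlation
  ranges, not to physical microvolt scales.
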