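# lfpspace

Spatial structure of multichannel local field potential (LFP)
correlations and its coupling to sleep state.

## What this is for

Chronic recordings from planar microelectrode arrays (a 10 × 10 Utah
array with 400 μm pitch and 96 wired sites, in the default
configuration) show that pairwise LFP correlations fall off with
inter-electrode distance toward a nonzero plateau, and that the *shape*
of that fall-off changes with brain state: during slow-wave sleep (SWS)
correlations are high at short range and decay steeply, while during
REM/awake periods they are lower overall and decay shallowly.
`lfpspace` implements that analysis as a tested pipeline:

1. **Spatial correlation functions.** For every non-overlapping 10 s
   epoch, Pearson correlations between all z-scored channel pairs are
   Fisher-transformed (z = atanh ρ) and averaged into 600 μm distance
   bins per source electrode, then pooled across sources weighting each
   bin by its pair count.
2. **Decay models.** Each epoch's z(d) profile is fit by count-weighted
   regression to an exponential f(d) = A·e^(−d/λ) (log-linearized),
   a power law f(d) = A·d^(−b), a Gaussian, and a line; the per-epoch
   (A, λ) scatter is summarized by a Type-2 (standardized major axis)
   regression.
3. **Sleep staging.** Multitaper power of the channel-averaged
   "virtual" LFP in the SO/delta (0.1–4 Hz) and gamma (30–60 Hz) bands
   is clustered with a 3-component Gaussian mixture; clusters map to
   SWS, REM/awake, and a null/transitional state by their delta–gamma
   balance.
4. **State coupling.** The fit-parameter ratio λ/A is compared with the
   gamma/delta power ratio (Pearson r with analytic CI, Type-2 slope
   with bootstrap CI), states are summarized by mean ± SD of λ, d′
   separation, and coefficients of variation, and a deliberately simple
   smooth-then-threshold SWS predictor is trained
   leave-one-session-out against a label-shuffle null.

Because such recordings are rarely shareable, the package ships a
first-class synthetic-data generator (`lfpspace.simulate`) whose ground
truth exercises every stage: per state, each frequency band is a sum of
a global component, a spatial field with covariance e^(−d/ℓ), and local
noise, giving the closed-form expected correlation
ρ\*(d) = (σ_g² + σ_s²·e^(−d/ℓ)) / (σ_g² + σ_s² + σ_n²).

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
360-epoch (1 h) default-regime synthetic session; each writes its
tables to `results/` (intermediates go to `scratch/`):

```bash
python analysis/01_simulate.py
python analysis/02_spatial_correlations.py
...
python analysis/06_threshold_classifier.py
```

Output of `02` (pooled correlation by distance):

```
pooled correlation: 0.797 at 600 um -> 0.443 at 4200 um
```

Output of `03` and `05` (decay fits and state coupling):

```
Type-2 (A, lambda) slope: -4179 um per z-unit, 95% CI [-4513, -3829], r = -0.83

    state   n  lambda_mean  lambda_sd  ratio_mean  ratio_cv
     NULL  12     5200.156    462.063    5345.051     0.072
REM_AWAKE 107     6646.856   1115.007    9685.571     0.154
      SWS 199     3909.510    431.138    2755.156     0.107

lambda/A vs gamma/delta: r = 0.942 [0.929, 0.954], d'(SWS, REM/awake) = 6.44
```

Reading this: SWS epochs have short decay constants (λ ≈ 3.9 mm) and
high initial values, REM/awake epochs long decay constants (λ ≈ 6.6 mm)
and low initial values, with the null state in between; the two ratios
co-vary strongly and the states separate by d′ ≈ 6.4. Staging recovers
the generative state of every valid epoch (`04`), and the one-parameter
threshold predictor reaches zero error against a ~45% shuffle null in
all three held-out sessions (`06`).

The same operations are available programmatically
(`lfpspace.spatial.session_distance_function`,
`lfpspace.decay.fit_all_epochs`, `lfpspace.staging.stage_epochs`,
`lfpspace.pipeline.run_pipeline`, …) and through the `lfpspace` CLI
(`simulate`, `preprocess`, `correlate`, `fit`, `stage`, `run`,
`report`).

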