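# Methods

This note documents the models, conventions, and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations of the inference.

## Porges–Bohrer RSA (module `rsa`)

The metric estimates cardiac vagal tone as the log heart-period variance in
the spontaneous-breathing band. The chain, for adults:

1. **Input.** Sequential R-R intervals in milliseconds (nearest-ms integers
   accepted, real values tolerated). R-peak detection and artifact editing
   are upstream of this package; inputs are assumed edited.
2. **Resampling (500 ms bins, 2 Hz).** The instantaneous heart period is a
   piecewise-constant function of time (interval k holds on
   [t_k, t_{k+1})). Each output sample is its exact time-weighted average
   over the bin, computed from the running integral. This conserves total
   time and was chosen over nearest-beat sampling or linear interpolation;
   the trailing partial bin is dropped.
3. **Detrending.** A 21-point cubic moving polynomial: at every sample, a
   least-squares cubic over the centered 21-sample window, evaluated at the
   center (the Savitzky–Golay smoother), is subtracted. For the first and
   last 10 samples the window is truncated asymmetrically and the fit is
   evaluated at the sample position, so no data are discarded; this
   boundary rule is a convention of this implementation.
4. **Band-pass (0.12–0.40 Hz).** Linear-phase FIR (Hamming-windowed sinc,
   127 taps by default at 2 Hz) applied forward–backward (zero phase, edge
   reflection padding). Two-pass response: mid-band gain within ±5% of
   unity; amplitude at 0.05 Hz and 0.55 Hz attenuated by far more than 90%.
   The tap count shrinks automatically to ⌊(n−1)/3⌋ (odd) on short series
   so the padding fits; the minimum useful recording is 60 s. The band
   edges are configuration — the 0.12–0.40 Hz default is the adult
   spontaneous-breathing band; no pediatric presets are shipped.
5. **Epoch log-variance.** Sample variance (n−1 denominator) of the
   filtered series in sequential non-overlapping 30 s epochs (60 samples),
   natural log, averaged over epochs. An epoch with variance below
   10⁻⁸ ms² is flagged and excluded from the mean (prevents ln 0); if every
   epoch is flagged (e.g. a metronomic heart) the result is NaN with a
   recording-level flag rather than an error, so mean heart rate is still
   reported. Mean heart rate is 60000 / mean(R-R).

**Accuracy and the spectral view.** For a noiseless in-band modulation of
amplitude A the chain recovers ln(A²/2) to within ±0.10 at 0.25 Hz, and a
50 ms slow trend (0.01 Hz) moves the estimate by < 0.1 ln-units. Two
systematic effects are worth knowing:

* *Resampling losses.* Beat-rate zero-order hold plus 500 ms bin averaging
  attenuate in-band power by sinc² factors (about −0.18 ln-units at
  0.25 Hz with an 800 ms mean heart period).
* *Detrend ripple.* The residual response |1 − H_SG(f)| of the 21-point
  cubic smoother is not flat in-band: measured residual amplitude gain is
  ≈ 0.48 at 0.12 Hz, ≈ 1.23 at 0.20–0.225 Hz, ≈ 0.87 at 0.30 Hz, ≈ 1.12 at
  0.25 Hz. This is intrinsic to the published detrender, not a filter
  defect.

Consequently PB_RSA agrees with spectral analysis *of the detrended series*
(ln of Welch power integrated over 0.12–0.40 Hz) to ≈ 0.02 ln-units on
stationary series — the sense in which the time-domain and
frequency-domain routes are equivalent — while comparison against the band
power of the raw resampled series shows the ripple and sinc effects
(≈ 0.2 ln-units, frequency dependent). Tests pin both facts. For the same
reason, adding a constant to all R-R intervals is *not* an exact invariance
at the R-R level (it stretches beat times and shifts the realized
modulation frequency across the ripple); the exact invariance — asserted to
1e-6 — holds for the processing chain applied to the evenly resampled
series, where the detrender annihilates constants and the band-pass has
zero DC gain.

## Functional networks (module `connectome`)

Inputs are region-averaged BOLD time series (time × region, with TR);
image-space preprocessing and atlas registration are out of scope. Cleaning
regresses each region on an intercept plus optional nuisance columns
(grey/white/CSF means) by OLS, band-passes the residual to 0.009–0.08 Hz
with the same zero-phase FIR design (65 taps at TR = 2 s after the
short-series rule), and only then drops censored timepoints — filtering
needs the contiguous grid; correlations use retained rows only.

Networks are Pearson correlations per region pair with negatives set to
zero and a zero diagonal ("unthresholded positive" weighting); the
downstream graph metrics cannot accommodate negative weights. A
zero-variance region is an error naming the region.

Metrics, all on the weighted matrix:

* **Clustering coefficient** — geometric-mean (Onnela-type) triangle
  intensity on weights rescaled by the network maximum,
  C_i = Σ_{j,h}(ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i(k_i−1)), with k_i the count of
  positive-weight neighbors and C_i = 0 when k_i < 2. This is the dominant
  convention in the brain-network literature for weighted clustering.
* **Efficiency** — edge length 1/w (standard for correlation weights;
  −ln w was considered and rejected as less common), Dijkstra shortest
  paths, E_i = mean over j≠i of 1/d_ij with unreachable pairs contributing
  zero; global efficiency is the mean of E_i.
* **Degree and strength** — degree counts strictly positive incident
  weights (it varies even without thresholding because negative
  correlations truncate to zero); strength sums them. The dyad table can
  use either as the "degree difference" covariate (`degree_mode`).
* **Modularity** — Louvain optimization of weighted Newman Q at
  resolution 1, seeded for reproducibility (networkx's implementation; tie
  breaking follows its seeded shuffle). The reported Q is the modularity of
  the returned partition.

Clustering and efficiency are verified against brute-force triple
enumeration and Floyd–Warshall on random small graphs to 1e−10.

## Dyadic mixed model (module `netmodel`)

One row per unordered node pair per subject-state. The outcome is the raw
truncated correlation weight, untransformed (no Fisher z), matching the
unthresholded-positive network definition. Covariates: endpoint averages of
clustering and efficiency, absolute degree difference, the network's Q,
state (0 = normal drinking reference, 1 = abstinent), PB_RSA, age, sex,
BMI. Continuous covariates are z-scored across all rows (so reported
estimates are on the standardized scale, and the RSA levels ±1 in the slope
report mean ±1 SD); state and sex stay 0/1. Degree difference and Q enter
as adjustments only, without interactions.

Fixed effects follow the full factorial of {clustering, efficiency} ×
{state, RSA} up to the three-way terms, plus the main effects and
adjustments — 17 terms including the intercept. Random effects: intercept
per subject plus (by default) an intercept per subject-state cell, encoding
within-subject dependence across the two sessions. Estimation is REML with
an L-BFGS fallback chain (maximum likelihood if REML fails; exact OLS when
the covariance is degenerate, e.g. noiseless simulations — where estimates
reproduce generating coefficients to 1e−8). Inference is Wald z: with
thousands to millions of dyads per model the normal approximation is the
appropriate convention (no Satterthwaite).

**Calibration, verified by simulation.** When the mixed model is the
generating process (30 subjects × 2 states × 50 nodes; σ_subj = 0.05,
σ_subj×state = 0.03, σ_resid = 0.10), the three-way clustering × state ×
RSA coefficient set to 0.012 is recovered with ≤ 10% relative bias, 95% CI
coverage in [0.90, 0.99], and null rejection at the nominal 5% level; its
null p-value is uniform. When dyads instead come from the *full pipeline*
(correlated region series → networks → metrics), dyads sharing a node are
positively dependent in ways subject-level random intercepts cannot absorb:
the model-based SE of the three-way term then overestimates its true
sampling SD (≈ 2× in our simulations), making the Wald test conservative —
the safe direction for type-I error, but a genuine limitation for power and
for interpreting near-threshold p-values on real data. Tests assert
uniformity under the generating model and non-inflation under the pipeline.

**Adaptive FDR.** Benjamini–Hochberg step-up with the number of true nulls
m₀ estimated by the lowest-slope rule (first increase of
l_i = (m+1−i)/(1−p_(i)) over sorted p-values; m₀ = min(⌊l_i⌋+1, m)).
Adjusted p-values are the classical BH values scaled by m₀/m, so forcing
m₀ = m reproduces BH exactly and the adaptive rejection set always contains
the classical one. It is applied across the fixed-effect p-values of the
single strength model, at q = 0.05 by default. On null uniform p-values the
observed FDR stays at the nominal level (verified over replicates).

**Report.** A per-effect table (Effect, Estimate, Standard Error, p-Value,
Adaptive FDR p-Value) and the implied strength-vs-metric slopes
slope(metric | d, r) = β_metric + β_metric×state·d + β_metric×RSA·r +
β_3way·d·r at d ∈ {0,1}, r ∈ {−1,+1}, with delta-method standard errors
from the fixed-effect covariance.

## Synthetic data (module `synthetic`)

* **R-R series.** Heart period h(t) = mean + A sin(2πf_resp t) +
  A_trend sin(2πf_trend t) + N(0, σ²), in milliseconds, with beats stepped
  as t_{k+1} = t_k + h(t_k) — adequate because h varies slowly over one
  beat, and simpler than inverting the integrated rate. Defaults: 800 ms
  mean, A = 20 ms at 0.25 Hz, 300 s. The analytic PB_RSA target is
  ln(A²/2). Not emulated: ECG waveforms, ectopy/artifacts, respiratory
  frequency drift.
* **Cohorts.** Zero-mean multivariate normal region series under a block
  correlation model (ρ_within inside blocks, ρ_between across; remainder
  nodes join the last block), two states per subject, with the population
  correlation matrix returned for oracle checks. Defaults are desk-scale
  (30 subjects, 50 nodes, 177 timepoints at TR = 2 s); a 268-region atlas
  run is configuration, not default. Not emulated: scanner drift, motion
  spikes, hemodynamic autocorrelation — so passing tests demonstrate
  statistical correctness of the machinery, not robustness to fMRI
  artifacts.
* **Dyad tables.** Outcomes drawn directly from the mixed model with
  specified β and variance components. Covariates are i.i.d. standard
  normal (state 0/1, sex Bernoulli(½)); the paper trail for real data gives
  no covariate distributions, and the topological coupling among
  clustering/efficiency/degree is deliberately ignored here — the full
  pipeline route covers that structure. Truth records (β, SDs, realized
  random effects) are returned for recovery tests.

Everything is seeded through `numpy.random.default_rng`; identical spec +
seed gives bit-identical output.

## Pipeline and problem sizes

The `run` pipeline chains all stages on synthetic data and writes CSV/TSV
plus a manifest (seed, package versions, SHA-256 of every output); reruns
with the same config and seed are byte-identical. Default demo scale is
5 subjects × 20 nodes. The simulation suites use 30 subjects × 50 nodes
with 50 recovery and 200 null replicates for the mixed-model calibration,
and 20 stationary recordings for the time/frequency comparison — sizes
chosen so the full verification runs in minutes on a single CPU while
keeping Monte Carlo error well inside the asserted tolerances.

## Known limitations

* The detrend ripple means PB_RSA is not a flat-band variance estimator;
  comparisons across groups with systematically different respiratory
  frequencies inherit a frequency-dependent gain of up to ±0.4 ln-units at
  the band edges.
* Wald z inference is conservative for topology covariates when dyad
  dependence goes beyond subject-level intercepts (see above); node-level
  crossed random effects would be the remedy but are out of scope.
* The exact filter family and boundary conventions of the reference
  implementation of the RSA metric are unpublished; this package pins its
  own choices by explicit gain contracts instead.
* No negative-weight network analysis, no thresholding pipelines, no
  per-edge mass-univariate testing, no spatial localization of effects.
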