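# vagalnet

Brain–body analysis tools for studying how cardiac vagal tone relates to
functional brain network organization across within-subject conditions (for
example, normal drinking versus short-term alcohol abstinence in everyday
drinkers). The package covers three stages, each usable on its own:

1. **Cardiac vagal tone** from 5-minute R-R interval recordings, quantified
   with the Porges–Bohrer respiratory sinus arrhythmia metric (PB_RSA).
2. **Functional brain networks** from region-averaged BOLD time series:
   nuisance regression, 0.009–0.08 Hz band-pass, Pearson correlation with
   negative truncation, and weighted graph metrics (clustering coefficient,
   global efficiency, degree/strength, Louvain modularity Q).
3. **Dyadic mixed-effects regression** relating every edge's strength to the
   endpoint topology, condition ("drinking state"), PB_RSA, and their
   interactions, with adaptive Benjamini–Hochberg FDR adjustment of the
   fixed-effect p-values.

A synthetic-data module generates R-R series with analytically known RSA,
block-correlated multi-subject region time series, and dyad tables drawn
from a mixed model with known coefficients, so every stage is testable
against ground truth without access to human data.

## The statistics in brief

**PB_RSA.** R-R intervals (ms) are resampled into 500 ms bins by
time-weighted averaging, detrended with a 21-point cubic moving polynomial
(local least-squares template subtracted from the series), band-passed to
the adult spontaneous-breathing band 0.12–0.40 Hz, and summarized as the
natural log of the filtered-signal variance in sequential 30 s epochs,
averaged over epochs:

    PB_RSA = mean_k  ln( Var_k[ BP(x − SG(x)) ] )    [ln ms²]

For a heart period modulated by `A·sin(2πft)` with `f` in-band, the target
value is `ln(A²/2)`.

**Edge-strength model.** For dyad (i, j) of subject s in state d ∈ {0, 1}
(0 = normal drinking, 1 = abstinent), with `w` the truncated positive
correlation:

    w_sdij = β₀ + β_d d + β_r RSA_s + β_dr d·RSA_s
           + β_C C̄ + β_E Ē + (two- and three-way interactions of C̄, Ē with d, RSA_s)
           + β_k |k_i − k_j| + β_Q Q_sd + β_age + β_sex + β_BMI
           + b_s + b_sd + ε,     b_s ~ N(0, σ²_subj), b_sd ~ N(0, σ²_subj×state)

where C̄ and Ē are the endpoint averages of clustering coefficient and
nodal efficiency. Continuous covariates are z-scored over all dyads; the
model is fit by REML (Wald z inference) and the fixed-effect p-values are
adjusted with the adaptive (lowest-slope m₀) Benjamini–Hochberg procedure.

## Worked example

Simulate a 5-minute recording whose heart period carries a 20 ms, 0.25 Hz
respiratory modulation (plus a slow 30 ms trend and 3 ms beat noise), then
compute PB_RSA:

```bash
$ vagalnet simulate-rr --amplitude 20 --freq 0.25 --noise-sd 3 \
    --trend-amplitude 30 --duration 300 --seed 7 --out rr.csv
analytic ln-variance target: 5.2983

$ vagalnet rsa --input rr.csv --band 0.12 0.40 --epoch 30 --out rsa.csv
pb_rsa=5.3542 ln(ms^2)  mean_hr=75.1 bpm  epochs=10
```

The recovered PB_RSA (5.354) sits within 0.06 ln-units of the analytic
target ln(20²/2) = 5.2983, and the slow trend is rejected by the detrending
step. The same chain is available in Python:

```python
from vagalnet import RRSimParams, simulate_rr_series, compute_pb_rsa

sim = simulate_rr_series(RRSimParams(mod_amplitude=20, mod_freq=0.25, seed=7,
                                     trend_amplitude=30, noise_sd=3))
result = compute_pb_rsa(sim.rr)
result.pb_rsa           # 5.354  (target ln(200) = 5.298)
result.mean_heart_rate  # 75.1 bpm
```

An end-to-end synthetic study (5 subjects × 2 states, 20 regions) runs from
a YAML config and writes per-stage CSVs plus a checksummed manifest:

```bash
$ vagalnet run --config demo.yaml
manifest: runs/demo/manifest.json
```

`model_report.csv` then holds one row per fixed effect — Effect, Estimate,
Standard Error, p-Value, Adaptive FDR p-Value — e.g. in this null demo
cohort (no built-in topology–RSA coupling) the drinking-state main effect is
the only structural signal:

```text
Effect,Estimate,Standard Error,p-Value,Adaptive FDR p-Value
Drinking State,-0.0585,0.0179,0.0011,0.0093
Clustering Coefficient,-0.0029,0.0112,0.79,0.99
...
```

and `slopes.csv` gives the implied strength-vs-clustering (and efficiency)
slopes at low/high RSA (−1/+1 SD) in each state, the quantity used to
visualize a three-way interaction.

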