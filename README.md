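# isomix

Nitrate source apportionment for waters receiving atmospheric nitrogen
deposition, from nitrogen and triple-oxygen isotope ratios of nitrate.

Remote alpine lakes receive reactive nitrogen whose origin — synthetic
fertilizer, fossil-fuel NOₓ, natural soil nitrate, septic effluent and
manure — cannot be told apart from concentrations alone. Two tracers can:
δ¹⁵N–NO₃⁻ separates terrestrial sources, and the ¹⁷O anomaly
Δ¹⁷O = δ¹⁷O − 0.52·δ¹⁸O is a conservative fingerprint of nitrate oxidized
in the atmosphere (AON), because only ozone photochemistry produces
mass-independent ¹⁷O enrichment. `isomix` implements the full analysis
chain:

* **Data reduction** (`isomix.corrections`): per-run OLS calibration
  against nitrate reference materials (USGS-32/34/35, GSI-NO-3), the
  mass-overlap correction δ¹⁵N_corrected = δ¹⁵N_cal − X_corr·Δ¹⁷O
  (X_corr = 0.1‰ per ‰ by default, estimable from a high-Δ¹⁷O standard),
  and inversion of the δ¹⁸O exchange with laboratory water
  (δ¹⁸O = (δ¹⁸O_meas − f·δ¹⁸O_water)/(1−f), f = 0.13 by default).
* **Bayesian mixing model** (`isomix.mixing`): for K sources with tracer
  profiles (μ_jk, ω_jk), each sample's tracer j follows
  X_ij ~ N(Σ_k p_k μ_jk, Σ_k p_k² ω_jk² + σ_j²) with p ~ Dirichlet(α) and
  σ_j ~ U(0, 20‰); random-walk Metropolis on log-ratio coordinates yields
  posterior draws of p, summarized as modal probability estimates (MPE)
  and 50/75/95% highest-density regions (HDR).
* **Budgets** (`isomix.budget`): the snow ammonium isotope mass balance
  δ¹⁵N_NH₄ = (δ¹⁵N_inflow·[total] − δ¹⁵N_snow·[NO₃⁻])/[NH₄⁺], scaling of
  a global tropospheric NOₓ emission budget to per-source shares of lake
  nitrate, and the anthropogenic roll-up (fertilizer share + fossil slice
  of the AON share).
* **Synthetic data** (`isomix.synth`): group tables (snow/inflow/lake)
  reproducing the study area's published summary statistics — including
  the Δ¹⁷O–δ¹⁸O correlation (R² ≈ 0.94) via a shared atmospheric-fraction
  latent variable — and exact mixture simulations for parameter-recovery
  testing.
* **IO + CLI** (`isomix.io`, `isomix.cli`): CSV readers/writers, the
  published sample-exclusion rules (NO₃⁻ > 1.6 μM, transitional snowmelt
  samples, missing Δ¹⁷O), YAML source configs, and an end-to-end pipeline.

## Worked example

Simulate a field campaign, fit the inflow group, and run the budgets:

```sh
isomix simulate --seed 1 --out samples.csv
isomix fit --samples samples.csv --group inflow --iterations 100000 \
    --seed 1 --out inflow.csv
isomix budget
```

The fit prints the apportionment table (percentages; MPE is the posterior
mode, the HDR columns are credible-interval bounds):

```
                    source  MPE  hdr50_low  hdr50_high  hdr75_low  hdr75_high  hdr95_low  hdr95_high
                       AON 15.0       14.0        16.0       14.0        16.0       12.0        18.0
       Fertilizer+Rain NH4 76.0       73.0        79.0       71.0        81.0       67.0        83.0
                  Soil NO3  4.0        1.0         8.0        0.0        11.0        0.0        15.0
Septic Effluent and Manure  0.0        0.0         2.0        0.0         4.0        0.0         7.0
```

The AON share (15%) is pinned almost entirely by Δ¹⁷O: the synthetic
inflows carry a mean anomaly of ≈ +3.4‰ against an atmospheric endmember
of ≈ +23.7‰, so roughly 15% of their nitrate retained atmospheric oxygen.
The narrow AON interval versus the wide Soil/Fertilizer intervals shows
the tracer geometry: Δ¹⁷O is decisive for AON, while the terrestrial
sources overlap in δ¹⁵N and trade off against each other.

`isomix budget` prints the NOₓ-budget table (e.g. fossil fuels: 40% of
tropospheric NOₓ, hence 10% of lake nitrate at a 24% AON share), the snow
ammonium balance (−4.5‰, within the fertilizer-ammonium range), and the
anthropogenic share 62 + 0.40·23 = 71.2%.

`isomix run --seed 0 --out outdir` executes the whole pipeline (filter →
per-group fits → budgets → provenance log).

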