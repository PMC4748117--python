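# Methods

## Model

`isomix` apportions the nitrate in a group of water samples among K
candidate sources using a Bayesian stable-isotope mixing model of the
SIAR family. For sample i and tracer j (by default δ¹⁵N and the ¹⁷O
anomaly Δ¹⁷O = δ¹⁷O − 0.52·δ¹⁸O),

    X_ij ~ Normal( Σ_k p_k (μ_jk + c_jk),  Σ_k p_k² ω_jk² + σ_j² )

with p the source-proportion vector on the simplex, (μ_jk, ω_jk) the
source tracer mean and s.d., c_jk an additive offset and σ_j a per-tracer
residual scale. The hierarchical formulation — latent per-source tracer
draws s_jk and per-sample residuals ε_ij — is marginalized analytically
into the variance above. The collapsed form has the identical marginal
likelihood, removes n·J + K·J latent parameters, and mixes far faster;
this is why no per-sample latent sampling is performed.

Assumptions inherited from the tracer system: Δ¹⁷O is conservative
(denitrification and assimilation shift δ¹⁵N/δ¹⁸O along mass-dependent
lines but leave the anomaly intact); nitrate tracers involve no trophic
fractionation step, so c_jk = 0 by default (the field is kept for
generality); sources are uncorrelated across tracers; mixing is linear in
concentration-independent proportions (no concentration weighting).

Identifiability: with two tracers the mixture-mean map pins at most three
proportions; with K = 4 sources a one-dimensional ridge remains, which is
constrained only by the simplex boundaries and the p²ω² variance term.
This is the correct behaviour of the model, and is why the terrestrial
sources (which overlap in δ¹⁵N) carry much wider credible intervals than
AON, which Δ¹⁷O pins directly.

## Priors, sampler and diagnostics

* p ~ Dirichlet(α), α = 1 (uniform over the simplex) by default.
* σ_j ~ Uniform(0, 20‰); the upper bound generously exceeds any plausible
  residual scale for these tracers and is configurable.
* Sampling: joint random-walk Metropolis on the additive-log-ratio
  transform of p (K−1 coordinates, with the Π p_k Jacobian) and on
  log σ_j (with the Π σ_j Jacobian). The isotropic proposal scale starts
  at 0.25 and is adapted every 200 burn-in iterations by
  `scale ← scale·exp(0.66·(rate − 0.3))`, targeting 20–40% acceptance;
  adaptation stops at the end of burn-in so the retained chain is a valid
  Markov chain.
* Defaults: 500,000 iterations, 50,000 burn-in, thinning chosen to retain
  ~10,000 draws. Sufficient statistics (per-tracer sums and sums of
  squares) make each iteration O(K·J), so the default run costs seconds.
* Convergence: `check_convergence` runs 4 chains at offset seeds and
  computes split-R̂ per proportion (warn above 1.05). The implementation
  is cross-checked against `arviz.rhat(method="split")` in the test
  suite.
* σ can be fixed (`sigma_fixed`) for oracle comparisons and for users who
  want SIAR's fixed-residual variant; whether the original analyses
  sampled or fixed σ is not documented, so sampled-per-tracer is the
  default.

## Posterior summaries

* **MPE** (modal probability estimate): 100 × the argmax of a Gaussian
  KDE of the proportion draws — Silverman bandwidth, boundary reflection
  at 0 and 1, 512-point grid. The mode estimator of the original software
  is undocumented; a reflected KDE is the standard choice for compactly
  supported samples and is validated against analytic Beta modes.
* **HDR** (highest density region), levels 50/75/95%: the density-quantile
  construction — KDE density evaluated at each draw, threshold at the
  empirical (1 − level) quantile of those densities, bounds the min/max of
  the draws at or above threshold. Nesting (HDR₅₀ ⊆ HDR₇₅ ⊆ HDR₉₅) holds
  by construction. For multi-modal posteriors the reported low/high span
  the whole region (matching the single-column reporting convention); the
  thresholded draw set is available programmatically.
* KDE densities are computed on a fine histogram (grid ~50× narrower than
  the bandwidth) smoothed with a Gaussian filter — numerically equivalent
  to the exact KDE at O(n) cost, which keeps million-draw HDRs under a
  second. Degenerate (point-mass) draw sets yield zero-width intervals.
* Display: percentages rounded half away from zero to integers; full
  precision is retained internally and in CSV output.

## Corrections

* δ¹⁵N mass overlap: ¹⁴N¹⁴N¹⁷O is isobaric with ¹⁵N¹⁴N¹⁶O at mass 45;
  after the mass-dependent (Craig) correction applied by the instrument,
  a residual mass-independent term proportional to Δ¹⁷O remains:
  δ¹⁵N_corr = δ¹⁵N_cal − X_corr·Δ¹⁷O, X_corr = 0.1‰/‰ by default and
  estimable from a high-anomaly standard as
  (δ¹⁵N_cal − δ¹⁵N_true)/Δ¹⁷O_cal. Samples whose Δ¹⁷O could not be
  measured keep their uncorrected δ¹⁵N and are flagged
  (`d15N_corrected_flag=False`) rather than dropped.
* δ¹⁸O water exchange: implemented as the exact inversion of two-component
  mixing with a single run-level exchange fraction f (default 0.13),
  (δ¹⁸O_meas − f·δ¹⁸O_water)/(1 − f). This is a deliberate
  simplification: no kinetic fractionation term, and f is treated as
  constant within a run. Laboratories that correct by standard bracketing
  can bypass this step and supply corrected values directly.
* Calibration: per-run, per-tracer OLS of accepted reference values on
  raw measurements; exact interpolation with two standards, residuals
  summing to zero with more. Reference values ship as an editable mapping
  because accepted assignments are revised occasionally.

## Budgets

* Snow ammonium balance: δ¹⁵N_NH₄ = (δ¹⁵N_inflow·([NH₄⁺]+[NO₃⁻]) −
  δ¹⁵N_snow·[NO₃⁻])/[NH₄⁺], assuming snow δ¹⁵N–NO₃⁻ equals total snow
  nitrate δ¹⁵N and negligible fractionation during nitrification. Point
  estimate only; no uncertainty propagation. The default snow nitrate
  concentration (6.73 μM) is back-derived from the published group means
  and should be replaced by a measured value where available.
* NOₓ budget: percent-of-NOₓ is computed from the actual column total of
  the emission table (59.8 Tg N/yr for the default budget), not its
  rounded display value; contributions are percent-of-NOₓ × AON share and
  sum exactly to the AON MPE before rounding. Display rounding follows
  the table convention: values ≥ 1 to integers, < 1 to one decimal.
* Anthropogenic share = fertilizer MPE + fossil-fuel-fraction × AON MPE;
  lightning, soil-emission and biomass-burning slices of AON are treated
  as natural or mixed and not counted.

## Synthetic data generator

The generator emulates a three-group field campaign (snow n = 12,
inflow n = 17, lake n = 12 — the usable sample counts) whose group means
and spreads match the published summary statistics: snow δ¹⁵N +0.9‰,
Δ¹⁷O +23.7 ± 5.6‰, δ¹⁸O +66.0‰, NH₄⁺ 5.8 μM; inflow δ¹⁵N −1.6‰,
δ¹⁸O +11.7‰, NO₃⁻ 28.7 ± 16.78 μM; lake δ¹⁵N +0.8‰, Δ¹⁷O +5.3‰,
δ¹⁸O +16.7‰, NO₃⁻ 1.6 ± 2.2 μM; inflow and lake NH₄⁺ identical at
0.9 μM. δ¹⁵N s.d.s are set to a quarter of the published ranges.

Each sample draws a latent atmospheric fraction a (truncated normal on
[0, 1], by rejection) and mixes a shared atmospheric endmember
(Δ¹⁷O 29.373‰, δ¹⁸O 81.2‰ — inside the observed non-polar atmospheric
range) with a terrestrial one (Δ¹⁷O 0‰, δ¹⁸O 2.5‰) in both oxygen
tracers, plus independent per-tracer noise. Using one latent fraction for
both tracers reproduces the Δ¹⁷O–δ¹⁸O correlation (combined-table
R² ≈ 0.94) mechanistically — both tracers track AON — instead of through
an imposed covariance. The endmember constants were fixed analytically
from truncated-normal moments so each group's expected Δ¹⁷O and δ¹⁸O
equal the published means: a terrestrial δ¹⁸O of 0‰ cannot reach the
inflow (11.7‰) and lake (16.7‰) means jointly with the published
anomalies, hence the 2.5‰ choice (well within the nitrification range).
Snow uses a ~ N(0.85, 0.15) rather than a ≡ 1 — snow nitrate is mostly,
not purely, atmospheric — which makes part of the printed 5.6‰ snow
anomaly spread covary with δ¹⁸O, as observed.

What the generator does not emulate: seasonality, catchment hydrology,
within-lake nitrogen cycling, censored/missing Δ¹⁷O values, analytical
drift. Passing recovery tests on this data therefore demonstrates the
correctness of the inference under the model's own assumptions, not
robustness to real-world model misfit. Note also that the synthetic
inflow group encodes the published inflow δ¹⁸O mean, which under the
two-endmember geometry implies an atmospheric fraction of ≈ 0.15 — a fit
to these synthetic inflows therefore correctly returns ≈ 15% AON, which
is not the (supplementary-data-based) published inflow apportionment.

`generate_mixture_samples` draws directly from the collapsed likelihood
at a known proportion vector, so recovery error in those experiments
isolates the inference. The reported lake proportion vector (24/35/34/2)
sums to 95%; as a simplex truth the AON entry is kept exact and the
terrestrial entries are rescaled pro rata to the remainder.

## Numerical choices and problem sizes

* Recovery experiments run 100,000 iterations with 10,000 burn-in
  (≈ 10,000 retained draws, a few seconds each); production fits default
  to the 500,000-iteration convention. Property tests use 20,000–80,000
  iterations, sized for tight Monte-Carlo tolerances.
* Likelihood exactness is asserted at 1e−9 against a brute-force normal
  density sum; mixing inversions round-trip at 1e−9; simplex validity of
  draws at 1e−9.
* Degenerate inputs: point-mass draw sets give zero-width HDRs and exact
  MPEs; zero source s.d. plus vanishing σ gives a −∞ initial density and
  a clear error; empty sample tables keep their schema.
* Ties in the KDE argmax resolve to the lowest grid point (numpy argmax
  convention); grid resolution (512 points on [0, 1]) bounds MPE
  quantization at ~0.2 percentage points.

## Known limitations

* No concentration-dependent mixing, tracer covariance within sources, or
  model selection.
* MPE at n ≈ 12–17 samples inherits substantial sampling variability from
  the data themselves (± a few percentage points for the Δ¹⁷O-pinned AON
  share, more for ridge-coupled terrestrial sources); single-realization
  recovery values should be read with that spread in mind.
* The exact source δ¹⁵N profiles used in the original analyses are
  supplementary-only; the shipped defaults are literature-range
  placeholders and materially affect terrestrial-source apportionment.
  Users reproducing a specific study should enter its source table via
  the YAML config.
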