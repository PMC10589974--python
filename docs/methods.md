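# Methods

## Model

Binary outcome `y_ij` for individual *i* in district *j*, with
`y_ij | p_ij ~ Bernoulli(p_ij)` and a structured additive predictor

```
logit(p_ij) = β₀ + Z'_ij θ + Σ_v f_v(x_ijv) + f_str(s_j) + f_unstr(s_j).
```

Assumptions: outcomes are conditionally independent given the predictor;
categorical effects are additive (no interactions); continuous effects are
smooth; the spatial field decomposes into a neighbour-correlated (intrinsic
CAR) and an exchangeable (iid) component — the convolution/BYM prior. The
Bayesian fit is unweighted by default: the survey weights inform the
design-based descriptives, while the structured model is fitted to the
sample likelihood (a weighted pseudo-likelihood is available behind
`weighted=True` and uses an approximate PG(w, η) augmentation; it is an
option, not the default, because weighting a hierarchical Bayesian model is
itself a modelling choice).

### Priors

| block | prior | default |
|---|---|---|
| intercept, fixed effects | Normal(0, `fixed_prior_var`) | variance 100 |
| spline coefficients | RW(d) penalty `γ'Pγ/τ²_spline`, `P = D'_d D_d` | d = 2 |
| structured field | intrinsic CAR, precision `K/τ²_str`, `K` = graph Laplacian | — |
| unstructured field | iid Normal(0, `τ²_unstr`) | — |
| every variance `τ²` | inverse-gamma(a, b) | a = b = 0.001 |

The inverse-gamma(0.001, 0.001) default is the historical default of the
structured-additive-regression software family; it is exposed in
`ModelSpec`/`StructuredAdditiveLogit` and can be replaced wholesale.

### P-spline construction

`n_knots` equally spaced knots span `[min(x), max(x)]` including both ends;
boundary knots are repeated `degree` extra times (clamped basis), giving
`(n_knots − 2) + degree + 1` basis functions. The clamped basis sums to one
everywhere on the span; the sampler relies on this to move the smooth's
level into the intercept exactly. The age default is 22 knots
(20 interior), cubic, second-order penalty.

### Sampler

Pólya-Gamma Gibbs (chosen over the IWLS-Metropolis used by classical
structured-additive software: both target the same posterior, but PG gives
rejection-free exact conditionals). Per sweep:

1. `ω_i ~ PG(1, η_i)` — exact Devroye alternating-series sampler
   (numba-compiled; the weighted option uses the truncated sum-of-gammas
   series for non-integer shape).
2. Joint Gaussian draw of *all* location parameters (fixed + spline +
   `f_str` + `f_unstr`) from the normal equations
   `Q = B'ΩB + P_prior`, `b = B'(y − ½)`, assembled by blocks: the dense
   block (intercept, dummies, spline) directly, the district blocks through
   group sums, followed by one Cholesky solve.
3. Sum-to-zero centring: the spline block and `f_str` each have their mean
   moved into the intercept (exactly, via partition of unity / a constant
   shift per district).
4. Inverse-gamma updates: shape `a + rank/2` with rank = `n_basis − d` for
   a spline block, `n_districts − n_components` for the CAR block,
   `n_districts` for the iid block; scale `b + quadratic_form/2`.

**Soft sum-to-zero constraints.** The difference penalty and the Laplacian
both annihilate constants, so "spline constant up, `f_str` constant down"
is an exactly flat direction of the joint conditional; numerically it makes
the draw wander to huge common offsets before recentring. A small precision
on each block mean (quadratic form `(Σγ)²/n_basis`, resp. `(Σf)²/J`) is
added to the prior. Because the density does not depend on those flat
coordinates and recentring removes them, the posterior of the identified
(centred) quantities is unchanged; the per-draw `Σ_j f_str(s_j)` residual
drops from ~1e−8 to machine precision.

Defaults: `n_iter=12000, burn_in=2000, thin=10, n_chains=2`; split-R̂ is
reported for the intercept and each variance component. A linear predictor
exceeding |40| logs a divergence warning; the draw is retained. Inputs are
canonically sorted before sampling, so results are invariant to record
order. All seeds derive from one `SeedSequence`; the numba PG stream is
seeded per chain.

### Derived quantities

* **aOR table** — `exp(posterior mean coefficient)` with equal-tailed
  2.5/97.5% bounds, reference levels shown as exactly 1; aORs rounded to 2
  decimals, φ to one decimal of a percent.
* **φ** — `τ²_str/(τ²_str + τ²_unstr)` at the posterior means, with a
  per-draw credible interval alongside; undefined (flagged) when both
  variances are zero.
* **DIC** — `mean(D) + pD`, `pD = mean(D) − D(η̄)` with the posterior mean
  taken on the linear-predictor scale; `pD` is exactly 0 for a degenerate
  posterior of identical draws.
* **District odds** — `exp(mean f_str + mean f_unstr)` centred to geometric
  mean one; districts without observations get a flagged NaN prevalence but
  still receive an odds value from the field.

## Design-based descriptives

* Prevalence: Hájek ratio with Taylor linearisation over strata/PSUs
  (with-replacement between-cluster variance). CIs are **logit-Wald** —
  design-based software in this area reports logit-transformed CIs and they
  respect [0,1] by construction; the tag is recorded in the estimate.
* A single-PSU stratum is an error naming the stratum, unless
  `single_psu="certainty"` treats it as a certainty unit (zero variance).
* Chi-square: Rao–Scott **first-order** correction (mean generalised design
  effect of cell and marginal proportions). The reference SRS variance uses
  the `n−1` denominator, which makes the statistic reduce *exactly* to
  classical Pearson under a trivial design (equal weights, one PSU per
  record, one stratum). Second-order corrections are out of scope; the
  first-order version is adequate for screening-level inference.
* Screening: the multivariable model's minimum Wald p per term against the
  nominal 0.2 threshold, with an `always_keep` list for literature-informed
  forcing; univariate p-values are computed and logged alongside.

## Moran statistics

Global I with permutation inference; the two-sided p-value
`(1 + #{|I*| ≥ |I|})/(n_perm + 1)` is the default and both one-sided
variants are always reported, because published Moran p-values do not
always state their sidedness. Local Moran uses conditional permutation
(unit held fixed, the rest permuted over its neighbour slots) and
quadrant labels HH/LL/HL/LH at `alpha`, NS otherwise; isolated districts
have `I_i = 0` and NS by the zero-lag convention. No multiplicity
correction is applied by default; `fdr=True` applies Benjamini–Hochberg and
logs it. The identity `Σ_i I_i = S0 · I` holds for either weight style.

## Synthetic generator

The generator is the model's exact inverse. What it emulates: sub-population
sizes (1947 women / 1371 men), the published categorical marginals, true
effect sizes equal to the published adjusted odds ratios, published variance
components (0.132/0.074 women; 0.130/0.211 men), a 30-district map (default
5×6 rook lattice standing in for 30 districts nested in 5 regions, with
strata as contiguous district blocks), and Bernoulli outcomes from the full
predictor. The CAR field is drawn in the Laplacian eigenbasis using only
positive eigenvalues (variance `τ²/λ_k`), which gives an exactly sum-to-zero
field; the standard-normal draws are taken even when `τ² = 0` so the stream
is continuous in `τ²`.

What it does **not** emulate — and hence what passing tests do not show
about real data: the real two-stage cluster sampling probabilities (weights
are equal by default, or Gamma(4, ¼) with mean one to exercise weighted
estimators), the true district adjacency, informative missingness (the
optional mechanism is completely at random; downstream handling is listwise
deletion with a logged count), item-specific reporting biases, and any
covariate dependence structure (covariates are drawn independently).

Intercepts of the ready-made configurations are calibrated
deterministically — Brent root-finding on the exact enumeration of
effect-carrying covariate cells crossed with 16 Gauss–Legendre nodes over
the uniform age range — to hit the published marginal prevalences (45.9%
women, 18.4% men). The small Jensen contribution of the spatial field is
ignored in this calibration; empirically the realised prevalence lands
within about one percentage point of target.

The default age curve is a mild mean-zero quadratic,
`0.3·(u² − 1/3)` with `u` the age scaled to [−1, 1]: a clearly-labelled
synthetic stand-in that exercises the smooth term (the published analysis
reports only a near-linear age summary, which pins down no curve shape).

## Experiment sizes

Chosen as the package's own test conditions: sampler-vs-quadrature checks
on 10 and 20 observations against 1-D/2-D quadrature oracles; parameter
recovery and 95%-interval coverage over 10 replicates of the women-scale
configuration at 4000 iterations per chain; DIC ordering over 20 replicates
at n=500 with a strong structured field (`τ²_str = 1.0`, `τ²_unstr = 0` —
the published analysis motivates the comparison but prescribes no
simulation design); Moran type-I calibration over 500 replicates on an 8×8
lattice with 199 permutations; screening calibration pooled over 500
replicates of two pure-noise candidates at n=400.

## Numerical choices and degenerate inputs

* Quantile/equal-interval class edges resolve ties to the **lower** bin;
  classes are 1-based; all-equal values collapse to a single class with a
  warning.
* Cholesky failure of the (jittered) normal equations adds 1e−8 to the
  diagonal once and retries.
* Constant covariates are rejected by the spline builder; constant values
  by Moran's I; degenerate (single-level or empty-margin) tables by the
  design chi-square; single-level covariates and collinear dummy columns by
  the conventional logistic fit (collinear columns are named via pivoted
  QR). Coefficients beyond |15| on the logit scale set a separation flag.
* Posterior-mean district effects under a *null* spatial field shrink
  strongly but their absolute size depends on the data realisation
  (per-district logit noise is ~0.15 SE at 5000 records over 30 districts);
  the test suite therefore checks the shrinkage ratio against the raw
  per-district deviations rather than a fixed narrow band.

## Known limitations

* First-order (not second-order) Rao–Scott correction.
* The weighted Bayesian option is a pseudo-likelihood with an approximate
  PG sampler for non-integer shapes, not a design-integrated model.
* No interactions, varying coefficients, or multinomial outcomes.
* DIC is the only model-comparison criterion implemented (matching the
  analysis this package operationalises); WAIC/LOO are not provided.
* Choropleth rendering is intentionally absent; the tested surface is the
  class/export tables, and GeoJSON export simply joins attributes onto
  caller-supplied geometries.
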