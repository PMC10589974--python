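# spatstar

Bayesian **s**patially structured **a**dditive logistic regression for
district-level risk mapping from complex survey data.

## The problem

Public-health surveys (DHS-style) record a binary outcome — here, whether a
respondent ever experienced intimate partner violence (IPV) — together with
individual and household covariates, the district of residence, and the
survey design (strata, clusters, weights). Two questions arise that a plain
logistic regression cannot answer together:

1. **Which factors are associated with the outcome**, allowing non-linear
   effects of continuous covariates such as age?
2. **How does residual risk vary over the map** — and is that variation
   spatially *structured* (neighbouring districts alike) or unstructured
   district-level heterogeneity?

`spatstar` implements the full pipeline: survey-weighted descriptives and
design-based chi-square screening, a fully Bayesian structured additive
logistic model with a convolution (BYM) spatial prior, variance
decomposition, DIC model comparison, Moran autocorrelation statistics with
LISA cluster labels, and choropleth class tables — plus a synthetic survey
generator with known ground truth so every stage is testable without any
restricted microdata.

## The model

For individual *i* in district *j* with binary outcome
*y<sub>ij</sub>* ~ Bernoulli(*p<sub>ij</sub>*):

```
logit(p_ij) = β₀ + Z'_ij θ + f(x_ij) + f_str(s_j) + f_unstr(s_j)
```

* `θ` — categorical fixed effects (diffuse Gaussian prior, variance 100);
* `f` — P-spline smooth: clamped cubic B-spline basis with a second-order
  difference penalty, read as a random-walk prior with variance
  `τ²_spline`;
* `f_str` — intrinsic CAR (Besag) field: prior precision `K/τ²_str` where
  `K = diag(degrees) − adjacency` is the Laplacian of the district graph;
* `f_unstr` — iid Normal(0, `τ²_unstr`) district effect;
* every variance component has an inverse-gamma(0.001, 0.001) hyperprior.

Posterior sampling is a rejection-free Gibbs sampler using exact
Pólya-Gamma data augmentation (`ω_i ~ PG(1, η_i)` makes the logistic
likelihood conditionally Gaussian). The location block — fixed effects,
spline coefficients and both spatial fields — is updated jointly; sum-to-zero
constraints on the spline and the structured field are enforced every sweep
with offsets absorbed into the intercept.

Key summaries: adjusted odds ratios `exp(posterior mean)` with equal-tailed
95% credible intervals; the structured share of spatial variance
`φ = τ²_str / (τ²_str + τ²_unstr)`; DIC = mean deviance + pD; per-district
adjusted odds `exp(f_str + f_unstr)` centred to geometric mean one.

## Worked example

```python
import spatstar as sp

graph = sp.make_lattice(5, 6)                      # 30-district stand-in map
cfg = sp.rwanda_like_config("women", graph, seed=42)
data = sp.simulate_survey(cfg)

prev = sp.weighted_prevalence(data, single_psu="certainty")
print(f"weighted prevalence: {100*prev.proportion:.1f}% "
      f"(95% CI {100*prev.ci_low:.1f}-{100*prev.ci_high:.1f})")

model = sp.StructuredAdditiveLogit(
    fixed=("decisions", "wealth", "controlling", "alcohol"),
    smooth=("age",), graph=graph,
    n_iter=4000, burn_in=1000, thin=3, n_chains=2, seed=1,
).fit(data.records)

print(sp.posterior_odds_table(model.result_).to_string(index=False))
print(f"phi (structured share): {model.phi_.structured_pct}%")
print(f"DIC: {model.dic_.dic:.1f} (pD = {model.dic_.p_d:.1f})")

obs = data.records.groupby("district", observed=False)["outcome"].mean()
res = sp.global_moran(obs.reindex(list(graph.labels)).to_numpy(), graph,
                      n_perm=999, seed=1)
print(f"Moran's I = {res.statistic:.4f} (two-sided p = {res.p_two_sided:.3f})")
```

Output:

```
weighted prevalence: 46.4% (95% CI 44.1-48.7)
       term        level  aOR  ci_low  ci_high  reference
  decisions not_together 1.00     NaN      NaN       True
  decisions     together 0.58    0.47     0.71      False
     wealth      poorest 1.00     NaN      NaN       True
     wealth       poorer 0.94    0.69     1.31      False
     wealth       middle 0.96    0.70     1.32      False
     wealth       richer 0.64    0.47     0.87      False
     wealth      richest 0.54    0.40     0.76      False
controlling           no 1.00     NaN      NaN       True
controlling          yes 5.70    4.61     6.96      False
    alcohol           no 1.00     NaN      NaN       True
    alcohol          yes 2.53    2.05     3.12      False
phi (structured share): 83.8%
DIC: 2289.3 (pD = 28.7)
Moran's I = 0.3372 (two-sided p = 0.028)
```

Reading the output: respondents with controlling partners have a posterior
adjusted odds ratio of 5.70 (the generator's true value is 5.80), partner
alcohol use 2.53 (true 3.11, within one realisation's sampling error);
making financial decisions together and higher household wealth are
protective. `φ = 83.8%` says most of this realisation's spatial variance is
structured (neighbour-correlated), consistent with the significantly
positive Moran's I of the observed district prevalences.

The same pipeline is available from the shell:

```
spatstar --seed 1 --out-dir out simulate --population women
spatstar --seed 1 --out-dir out describe --data out/dataset.csv
spatstar --seed 1 --out-dir out fit --data out/dataset.csv --n-iter 4000 --burn-in 1000
spatstar --seed 1 --out-dir out moran --values out/values.csv
spatstar --seed 1 --out-dir out map --values out/values.csv --threshold 0.5
```

## Graph file formats

Adjacency is data, not geometry: `read_graph` / `write_graph` support

* **edge_list** — one whitespace-separated label pair per line; `#` starts a
  comment; a line with a single label declares a district without an edge
  (this is how isolated districts are written).
* **gra** — a neighbours-list dialect used by areal-modelling software
  (several variants exist; this one is fixed as follows): line 1 is the
  district count `n`; then for each district three lines — its label, its
  neighbour count, and a line of 0-based neighbour indices (empty for
  degree 0). Adjacency must be symmetric; asymmetric files are rejected.

Writers emit both dialects canonically (sorted labels, sorted neighbour
lists).

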