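# comorbmap

Bayesian geoadditive multinomial regression and Getis-Ord Gi\* hotspot
mapping of **childhood illness comorbidity** — the number (0–3) of
concurrent illnesses (diarrhea, fever, cough) a child experienced in a
two-week survey recall window, as collected by Demographic and Health
Surveys (DHS). The package is aimed at epidemiologists analysing
georeferenced child-morbidity survey data who want spatially smoothed,
covariate-adjusted risk estimates rather than region-by-region tabulations.

Because the underlying survey microdata (2016 Ethiopia DHS, 8742 children,
11 regions) are access-restricted, the package ships a synthetic generator
that reproduces the published statistical structure — outcome margins,
covariate margins, cluster-in-region design, a single-peak age effect and
spatially correlated region effects — with known ground truth, so every
stage of the pipeline is testable end to end.

## Model

For child *j* in region *i*, the outcome category *l* ∈ {0, 1, 2, 3} follows
a baseline-category (multinomial) logit with category 0 ("no illness") as
reference:

```
π_ijl = exp(η_ijl) / (1 + Σ_{k=1..3} exp(η_ijk)),     η_ij0 ≡ 0
η_ijl = H_ij β_l + f_l(age_ij) + f_str,l(region_i) + f_unstr,l(region_i)
```

* `H_ij β_l` — dummy-coded fixed effects of ten categorical risk factors
  (sex, anemia, breastfeeding, toilet type, place of delivery, mother's work
  status, household size, mother's education, birth order, water source);
  flat priors by default, `exp(β)` reported as odds ratios.
* `f_l(age)` — a P-spline: cubic B-spline basis (20 interior knots) whose
  coefficients carry a second-order random-walk prior with variance τ².
* `f_str,l` — an intrinsic Markov-random-field (ICAR) prior over the region
  adjacency graph: each region's effect is conditionally Gaussian around the
  mean of its neighbours with variance τ²_str / N_s.
* `f_unstr,l` — iid Gaussian region effects, variance τ²_unstr.
* All variances get inverse-gamma IG(a, b) hyperpriors, default a = 1,
  b = 0.005.

Inference is a pure Gibbs sampler: the multinomial is decomposed into
per-category conditional binary logits and augmented with Polya-Gamma latent
variables, giving Gaussian full conditionals for every coefficient block and
inverse-gamma full conditionals for every variance. A metropolized IWLS
update is available as an alternative (`method="iwls"`). Six predictor forms
M1–M6 (from fixed-effects-only up to the full model) are compared by DIC
(`DIC = D̄ + pD`, `pD = D̄ − D(θ̄)`).

Cluster-level hotspot detection uses the Getis-Ord Gi\* statistic on
per-cluster comorbidity intensity with k-nearest-neighbour weights
(self-weight included); |z| with two-sided Gaussian p < 0.05 classifies
clusters as hotspots ("high") or coldspots ("low").

## Worked example

```python
import numpy as np
from comorbmap import (SimulationConfig, simulate_dataset, lattice11_graph,
                       fit, MCMCOptions, model_spec, dic, or_summary, hotspots)

graph = lattice11_graph()                       # synthetic 11-region lattice
ds, truth = simulate_dataset(SimulationConfig(seed=1), graph)
print(ds.n, ds.category_counts())               # 8742 [6398 1260  790  294]

s = fit(ds, graph, model_spec("M5"),            # fixed + smooth + structured
        options=MCMCOptions(iterations=2000, burnin=600, thin=7, seed=1))
print(round(dic(s, ds, graph).dic, 1))          # 14087.4

t = or_summary(s)
row = t[(t.term == "sex=female") & (t.category == "one illness")].iloc[0]
print(round(row["or_mean"], 2),                 # 0.78  (truth exp(-0.17)=0.84)
      round(row["ci_2.5"], 2), round(row["ci_97.5"], 2))   # 0.68 0.89

h = hotspots(ds).by_region()                    # Gi* at cluster level
print(h.loc[h.region_id == "Tigray"].to_dict("records"))
# [{'region_id': 'Tigray', 'overall': 63, 'high': 0, 'low': 0,
#   'insignificant': 63}]
```

The DIC (~14.1k at n = 8742) sits on the same scale as a four-category
multinomial fit of this size should (a saturated-null deviance of
2n·ln 4 ≈ 24.2k, cut down by the strongly unbalanced outcome margins), and
the 95% interval for the female odds ratio covers its generating value. At
the default spatial variance (τ²_str = 0.1) no cluster reaches Gi\*
significance on this seed — spatial heterogeneity of a few tenths on the
log-odds scale is real but diffuse; the planted-hotspot experiment
(`comorbmap.experiments.planted_hotspot_experiment`) shows the analysis
localises a genuinely elevated region reliably.

The numbered scripts under `analysis/` run the same pipeline as a narrative:
`01_simulate` → `02_descriptive_tables` → `03_hotspots` →
`04_model_comparison` → `05_posterior_report`, writing tables to `results/`.

A `comorbmap` console command exposes the same steps
(`simulate`, `fit`, `compare`, `hotspot`, `report`, `graph-convert`).

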