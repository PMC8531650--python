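# comorbtraj

Matched case-control analysis of comorbidity trajectories in
administrative claims data.

For researchers working with claims-style records (persons, coverage
spells, dated diagnosis codes), `comorbtraj` builds a matched cohort of
incident Alzheimer's disease (AD) cases and AD-free controls, scores
three-digit ICD-9 comorbidity categories per yearly interval over the five
years before the index date, models each category's prevalence trajectory,
and clusters categories by how their trajectories diverge between groups.
A seeded synthetic claims generator with planted ground truth makes every
stage testable without licensed data.

## The model

For comorbidity *i*, member *j* (case or control) and yearly interval
*k* = 1..5 before the index date, presence is modelled marginally as

```
logit p_ijk = η_i + α_i·AD_j + β_i·(t_k − t̄) + γ_i·AD_j·(t_k − t̄)
```

with t = 6 − k (time increases toward the index date) and t̄ the mean
follow-up time. The model is fitted per comorbidity by generalized
estimating equations (GEE) with an unstructured (default), exchangeable,
or independence working correlation across the five yearly outcomes, and
Huber–White sandwich standard errors clustered on member. α is the
case-vs-control log-odds difference at the mean follow-up time; γ — the
difference in per-year log-odds slopes — is the trajectory-divergence
parameter. Wald p-values for α and γ are Benjamini–Hochberg adjusted
across comorbidities.

Each comorbidity is then summarized by four metrics (α, signed −log₁₀ p(α),
γ, signed −log₁₀ p(γ)), z-standardized, rotated by PCA, and grouped by
Ward hierarchical clustering on Euclidean distances over all principal
components, cut at k = 5 clusters by default.

See `docs/methods.md` for conventions, estimation details and limitations.

## Worked example

```python
import numpy as np
import comorbtraj as ct

# 2,000 matched pairs, 175 comorbidities planted across five archetypes
config = ct.SimConfig(n_pairs=2000, seed=42)
panel, truth = ct.simulate_panel(config)

results = ct.TrajectoryGEE(panel).fit()
print(results.frame()[["comorbidity", "alpha", "se_alpha",
                       "gamma", "se_gamma", "q_gamma"]].head(4).to_string(index=False))

clustering = results.cluster(k=5)
print("PC variance shares (%):", np.round(100 * clustering.variance_explained, 1))
print("cluster sizes:", np.bincount(clustering.labels)[1:])
```

prints

```
comorbidity    alpha  se_alpha    gamma  se_gamma      q_gamma
        100 1.232055  0.033589 0.433650  0.023772 8.399341e-73
        101 1.059476  0.032324 0.327334  0.023160 2.299495e-44
        102 1.166438  0.033317 0.418869  0.023939 3.756938e-67
        103 1.174176  0.032597 0.378481  0.023080 2.444343e-59
PC variance shares (%): [84.7 10.9  4.2  0.2]
cluster sizes: [18 19 22 65 51]
```

Categories 100–103 come from the "rapidly-diverging" archetype
(generating α = 1.2, γ = 0.40 before jitter): the fitted case-vs-control
log-odds differences of ≈ 1.1–1.2 and divergence slopes of ≈ 0.33–0.43
per year recover the planted values within a few robust SEs, with q-values
far below any conventional threshold. The five recovered cluster sizes
(18/19/22/65/51) match the planted archetype sizes exactly (adjusted Rand
index 1.0 against truth at this sample size).

The same analysis runs from raw tables via the CLI:

```sh
comorbtraj run-all --out-dir run1 --seed 7 --n-pairs 500
comorbtraj simulate --out-dir data --seed 7 --n-pairs 500   # or stage by stage
comorbtraj build-cohort --input-dir data
comorbtraj match --input-dir data --seed 7
comorbtraj fit --input-dir data
```

Stage outputs are delimited text (pairs, prevalence table, per-comorbidity
fits, metric matrix, PC scores, linkage, cluster labels) plus a JSON
manifest with attrition counts.

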