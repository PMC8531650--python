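# Methods

## The problem

`comorbtraj` implements a matched case-control analysis of comorbidity
*trajectories* in administrative claims data. The motivating question is
whether the mix of diagnoses recorded for a person in the five years before
an incident Alzheimer's disease (AD) diagnosis differs — in level and in
time course — from that of demographically matched AD-free individuals, and
whether comorbidities fall into interpretable groups by that behaviour.

The pipeline has six stages, each usable on its own:

1. **Cohort.** Cases are persons with ≥ 2 AD claims (ICD-9-CM 331.0 or
   ICD-10-CM G30.x) on separate service dates, the first at age ≥ 50, with
   continuous enrollment covering the five years before the first AD claim
   (the *index date*). Coverage spells separated by ≤ 62 uncovered days are
   merged before the continuity check; merged spans are clipped to the study
   window (2000-01-01 .. 2016-12-31). Eligible controls are AD-claim-free
   and continuously enrolled over the case's window, and inherit the case's
   index date.
2. **Matching.** 1:1 exact matching without replacement on six variables:
   sex, year of birth, plan type, relationship to plan holder, industry,
   region. Selection within a case's exact-key pool is uniform at random.
3. **Coding.** ICD-10 codes are mapped to ICD-9 by configurable
   longest-prefix lookup, then all codes are reduced to three-digit ICD-9
   categories (four characters for E-codes). Presence of a category is
   scored per yearly interval k = 1..5 before the index date; categories
   with pooled five-year occurrence < 5% are dropped.
4. **GEE.** Per category, a marginal logistic model over the five yearly
   indicators: logit p = η + α·AD + β·(t − t̄) + γ·AD·(t − t̄), fitted by
   generalized estimating equations with a working within-person correlation
   and the sandwich covariance clustered on person. α (with centered time)
   is the case-vs-control log-odds difference at the mean follow-up time;
   γ is the difference in per-year slopes — the trajectory divergence.
5. **Multiple testing.** Two-sided Wald p-values (robust z, normal
   reference) for centered α and γ; Benjamini–Hochberg FDR across
   categories, by default separately within the α family and the γ family.
6. **Clustering.** Each category contributes four metrics: centered α,
   signed −log₁₀ p(α), γ, signed −log₁₀ p(γ). The matrix is z-standardized,
   rotated by PCA (all components kept), and grouped by Ward hierarchical
   clustering on Euclidean distances in PC space, cut at k clusters
   (default 5). Cluster ids are renumbered so cluster 1 has the largest
   median γ evidence.

## Model and estimation details

*Time coding.* Interval k = 1 is the year immediately before the index
date. The time covariate is t = 6 − k, so t increases toward diagnosis and
a positive γ means the comorbidity rises toward the index date faster in
cases. Centering uses t̄ = mean of observed t (3 for complete panels).
Setting `t_bar=0` gives the uncentered parameterization; `centered_alpha`
recovers the centered effect as α + γ·t̄ with a delta-method SE
(var = var α + t̄² var γ + 2 t̄ cov(α, γ)), and agrees with a centered refit
to solver precision — this reparameterization identity is kept as a
cross-check.

*Solver.* Fisher scoring on the estimating equations, vectorized over
members (the panel is balanced: every member contributes the same
intervals). The working correlation (unstructured, exchangeable or
independence) is re-estimated from Pearson residuals each iteration with a
p-parameter degrees-of-freedom correction; off-diagonals are clamped to
|r| ≤ 0.99. Convergence: max parameter change < 1e-10 (relative).
Robust covariance is the usual bread⁻¹·meat·bread⁻¹ with member-level score
outer products; the dispersion factor cancels. On divergence or a singular
solve the fit falls back unstructured → exchangeable → independence; if
every structure fails (e.g. an all-zero outcome), the category is flagged
non-converged and excluded from q-values and clustering. The solver matches
statsmodels' GEE (all three structures, coefficients and robust SEs) to
~1e-13 on shared inputs, and with one observation per member reproduces the
ordinary logistic MLE.

*Interval convention.* Interval k covers (index − k·365.25 d,
index − (k−1)·365.25 d]; claims dated exactly on the index date are
excluded (pre-diagnosis semantics). The convention string is carried on
the panel object.

*Multivariate choices.* The −log₁₀ p metrics are signed by the direction of
the effect so protective and adverse associations separate (unsigned
available by flag); underflowing p-values are floored at 1e-300. Metrics
are z-standardized before PCA because effect and evidence columns have
incommensurate scales (covariance PCA by flag). Since all PCs are retained
and standardized PCA is a rotation, clustering in PC space is equivalent to
clustering the z-scored metrics; the rotation is kept because the PC
variance shares are themselves a reported output. Ward linkage uses scipy's
implementation (Lance–Williams update, squared-Euclidean merge cost,
deterministic nearest-neighbor chaining), equivalent to the Ward.D2
convention. Percentages in prevalence and demographic tables are rounded
half-up (1 and 2 decimals respectively), computed exactly from integer
counts.

## The synthetic claims world

The generator plants five trajectory archetypes and draws per-comorbidity
parameters (η, α, β, γ) as archetype means plus N(0, 0.03²) jitter. The
defaults (counts 18/19/22/65/51 comorbidities):

| archetype | η | α | β | γ | character |
|---|---|---|---|---|---|
| rapidly-diverging | −1.4 | 1.20 | 0.06 | 0.40 | prevalent, strongly case-elevated, steep divergence |
| low-prevalence-diverging | −2.6 | 0.30 | 0.04 | 0.28 | rare, modest elevation, clear divergence |
| moderately-diverging | −2.0 | 0.80 | 0.03 | 0.16 | moderate elevation and divergence |
| null | −1.0 | 0.00 | −0.02 | 0.00 | no group difference, slight decline |
| elevated-stable | −0.6 | 0.45 | 0.02 | 0.00 | common, elevated, parallel trajectories |

These were chosen once so that archetypes are separated in the
(α, γ, evidence) metric space by amounts a clustering method ought to
resolve at a few thousand pairs, while spanning the qualitative cluster
types the analysis is meant to distinguish (diverging vs stable, common vs
rare, null). Yearly outcomes are independent Bernoulli draws from the
logit-linear law; a Gaussian-copula option (`within_person_corr`) induces
exchangeable within-person dependence for robustness checks — the marginal
law is unchanged. Real within-person serial correlation of claims
indicators is unknown; independence is the default and both regimes are
exercised in tests.

`simulate_panel` emits the member × comorbidity × year indicator array
directly (fast path for estimation studies). `simulate_claims` emits full
persons/spells/claims tables: every case carries two AD claims on separate
days (ICD-9 331.0, or G30.x when dated after 2015-10-01), 5+ years of
pre-index coverage possibly split by one allowed ≤ 62-day gap; each case is
cloned into `controls_per_case` AD-free persons with the identical matching
key (so exact matching always succeeds); distractor persons violate exactly
one cohort rule each (a 70+ day gap inside the lookback, a single AD claim,
only four years of pre-index coverage). Comorbidity claims are placed
uniformly inside the interval whose indicator fired, and are emitted as
ICD-9; the ICD-10 mapping path is exercised by the AD claims and by unit
tests. Demographics are sampled independently of archetypes (matching
removes them by design).

What the generator does *not* emulate: realistic ICD code frequencies or
co-occurrence, care-seeking intensity differences (surveillance bias),
mortality/disenrollment related to disease, drug or procedure codes, and
non-linear trajectories. Passing tests therefore demonstrate correctness of
the estimators and pipeline under the stated generating law, not robustness
to those real-data features.

## Problem sizes used in the checks

The packaged checks run at desk scale, chosen once: prevalence-law
convergence at 20,000 pairs; sandwich-vs-bootstrap calibration at 500 pairs
with 1,000 stratified member-level bootstrap replicates; parameter recovery
at 10,000 pairs across all 175 default comorbidities; end-to-end cluster
recovery at 5,000 pairs × 20 replicates (ARI ≥ 0.8 against the planted
archetypes in ≥ 90%); the full claims-world pipeline at a few hundred
pairs. A real claims study is two orders of magnitude larger in members but
identical in structure.

## Known limitations

- Age is computed as index year − birth year (claims carry birth year, not
  date of birth).
- Both qualifying AD claims are not required to be at age ≥ 50 — only the
  first (the index claim).
- Persons who ever become cases are excluded from all control pools, even
  before their diagnosis (configurable in principle; fixed here to avoid
  status ambiguity).
- Greedy randomized matching can leave cases unmatched when exact-key pools
  overlap; unmatched cases are dropped with a logged count. No optimal
  assignment is attempted.
- The bundled ICD-10→ICD-9 map covers only the codes used here; real
  analyses must supply a full mapping file.
- `fcluster(..., criterion="maxclust")` can return fewer than k clusters on
  exactly tied merge heights; with continuous metrics this does not occur.
- No small-sample covariance corrections; the robust z reference assumes
  large member counts.
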