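# biopriority

Expert-weighted multi-criteria prioritization of surgical waiting lists,
with unsupervised patient stratification and a stochastic clinical-impact
simulator.

## The problem

Elective-surgery waiting lists are commonly managed first come, first
served. For heterogeneous specialties such as ENT this ignores how sick,
how limited and how socially vulnerable each patient actually is. This
package implements a transparent alternative for waiting-list teams and
health-services researchers: a composite biopsychosocial priority score
built from expert judgment, a cluster-based stratification into High /
Medium / Low priority groups, and a Monte-Carlo simulator that quantifies
what prioritized scheduling changes relative to the chronological baseline.

## The model

**Weights (direct-rating AHP).** Each of *m* physicians scores each of *n*
decision variables on 0–10 for its relevance to surgical priority. With
rating μ_im, variable *i* receives weight

    w_i = (Σ_m μ_im) / W,    W = Σ_i Σ_m μ_im,    Σ_i w_i = 1.

Inter-rater agreement is summarized by pairwise Cohen's κ on binned scores,
and robustness by a ±10 % one-at-a-time weight perturbation analysis.

**Normalization (expert shares).** Every variable carries expert clinical
impact scores per level (ordinal/categorical), per clinical interval
(continuous) or per state (binary). A raw patient value maps to its level's
share of the variable's total impact, e.g. for a 3-level variable scored
(2, 5, 9) the top level maps to α = 9/16. This yields the normalized
decision matrix α ∈ [0,1]^{n×N}.

**Score.** The composite priority of patient *p* is the weighted sum
s_p = Σ_i w_i α_ip (vector form **s** = **w**ᵀα). Linearity makes the score
traceable: each variable contributes exactly w_i α_ip.

**Stratification.** Patients are grouped by K-means on their normalized
profiles (or PAM k-medoids on a Gower dissimilarity for the mixed-type raw
data), K chosen by silhouette/elbow; clusters are ranked by mean score into
High/Medium/Low. A PCA projection and a permutation MANOVA on Wilks' lambda
(with Mahalanobis centroid distances) document the separation.

**Simulation.** While waiting, a patient's latent clinical risk R(t) on a
0–10 scale follows a Gamma distribution whose shape α₀ + δ·e^{λt} grows
with waiting time; urgent hospitalization is a per-day Bernoulli event with
logistic probability 1/(1+exp(−(γR−θ))) (γ = 1.8, θ = 4.5); urgent
admissions occupy Poisson(λ_D = 3.8) bed days. Chronological and
score-prioritized scheduling are compared over Monte-Carlo replicates with
95 % percentile confidence intervals on four indicators: exit risk, %
urgently hospitalized, bed days per hospitalized patient, and High-group
waiting time.

A synthetic-cohort generator (205 patients, 20 mixed-type variables, a
latent 3-group severity structure, 7 raters, binary demographics) makes the
whole pipeline testable without patient data, and a demographic-parity
audit (chi-square / Monte-Carlo independence test, Holm-adjusted across
attributes) checks that priority groups do not track protected attributes.

## Worked example

```bash
biopriority synth --seed 7 --out-dir run/
biopriority weights   --ratings run/ratings.csv --registry run/registry.yaml \
                      --out run/weights.csv --kappa
biopriority normalize --cohort run/cohort.csv --registry run/registry.yaml \
                      --out run/alpha.csv
biopriority score     --alpha run/alpha.csv --weights run/weights.csv \
                      --out run/scores.csv
biopriority cluster   --alpha run/alpha.csv --scores run/scores.csv \
                      --k 3 --seed 42 --out-dir run/
biopriority fairness  --labels run/clusters.csv --cohort run/cohort.csv \
                      --attributes dem_ses,dem_rural
```

prints, among other things:

```
wrote 20 weights to run/weights.csv (sum = 1.000000000)
mean pairwise Cohen's kappa: 0.460
scored 205 patients (High 69, Medium 69, Low 67)
K=3 (euclidean): objective 76.8844, silhouette 0.471, separation p = 0.0010
attribute  statistic  p_value       test  p_holm
  dem_ses     3.7685   0.1519 chi-square  0.1519
dem_rural     6.0962   0.0475 chi-square  0.0949
```

Reading: the seven simulated raters agree substantially after noise
(κ = 0.46 at rater SD 1); the 205 synthetic patients split into three
clusters whose separation a 999-permutation MANOVA rates at the smallest
attainable p (0.001); the silhouette 0.47 supports K = 3; and neither
demographic attribute shows a parity violation after Holm adjustment at the
5 % level. `run/scores.csv` holds each patient's composite score and label
(e.g. `P0001, 0.552, High`), and `run/diagnostics.json` records that the
first two principal components carry 67.0 % + 9.4 % of the profile
variance.

The same steps are available as a library — `AlphaNormalizer`,
`PriorityScorer` and `PriorityKMeans` are scikit-learn-style estimators,
and `monte_carlo_compare` runs the scheduling comparison:

```python
import biopriority as bp
from biopriority.synth import entry_days_from_cohort

registry = bp.default_registry()
cohort, truth = bp.generate_cohort(bp.SynthesisConfig(seed=7), registry)
alpha = bp.build_alpha_matrix(cohort, registry)
scores = bp.priority_score(bp.panel_weights(), alpha)
labels = bp.assign_priority_labels(scores).labels
summary = bp.monte_carlo_compare(
    entry_days_from_cohort(cohort), scores, labels == "High",
    bp.SimulationConfig(seed=1, n_iterations=200),
)
print(summary.table.round(2))
```

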