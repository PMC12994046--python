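# Methods

This note documents the models implemented in `biopriority`, the numerical
and design choices made where the methodology is genuinely open, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## Decision variables and normalization

A prioritization framework is an ordered registry of mixed-type
biopsychosocial variables. Four kinds are supported: ordinal and
categorical (a fixed set of levels), continuous (a contiguous set of
half-open clinical intervals `[lo, hi)`, the last interval closed so the
domain maximum is representable), and binary. Every level, interval or
binary state carries a positive expert impact score on the 1–10 scale; a
raw value is normalized to its level's *share* of the variable's total
impact. Shares over a variable's levels sum to exactly 1 by construction,
so a multi-level variable's normalized value is capped at
`score_max / Σ scores` — the interval [0, 1] is an envelope, not an
attained range. Where per-level scores come from several raters they are
aggregated by arithmetic mean before the share is formed.

The shipped default registry contains the 20 ENT panel variables (severity,
urgency, physician-indicated maximum wait, sleep disorder, time on list,
expected surgical benefit, study/work capacity, comorbidity risk, family
participation, affected area, other pathologies, diagnosis group, other
limitations, caregiver need/duties, pain, residence area, transfer
difficulty, clinical-bed need). The kinds, level codings and per-level
impact scores in that file are package defaults chosen to be clinically
ordered and plausible; institutions are expected to override them. The
published panel *weights* for these variables are shipped separately
(`data/ent_panel_weights.csv`) and are used exactly as printed: they sum to
1.001 because of publication rounding, and the loader deliberately does not
renormalize them, because downstream traceability statements (a 0.1 urgency
shift moves the score by 0.076 × 0.1 = 0.0076) hold for the printed values.

### Missing data

Patients missing strictly more than 10 % of registry variables (i.e. 3+ of
20) are excluded and reported with their missing fraction; the comparison
is strict, so exactly 2 of 20 is retained. Remaining gaps are imputed
within clinically homogeneous subgroups keyed by (age band, diagnosis) —
age bands default to decades and are configurable — using the subgroup
mean for continuous variables and the subgroup mode otherwise, falling
back to the whole cohort when a subgroup has no donors. Mode ties break by
declared level order, which makes imputation deterministic. Because the
continuous domain is an interval and donors lie inside it, imputed values
are always in-domain, and the procedure is idempotent.

## Weights, agreement and stability

Weights use the direct-rating formulation of the analytic hierarchy
process: `w_i = row_sum_i / grand_total`. There are no pairwise-comparison
matrices and hence no eigenvector consistency machinery; scale invariance
(multiplying all ratings by c > 0 changes nothing) and monotonicity
(raising one rating strictly raises that variable's weight) follow
directly.

Cohen's κ is computed for every rater pair after discretizing the 0–10
scores into `n_bins` equal-width bins (default 5; the elicitation scale is
continuous and no binning convention is canonical, so it is a parameter).
A pair in which both raters are constant in the same bin has chance
agreement 1; κ is defined as 1 there and the pair is flagged.

The stability analysis perturbs each weight by ±10 % one at a time,
renormalizes the whole vector to sum 1 (only relative weights matter for
ranking, and renormalization keeps the unit-sum contract valid), reruns
scoring, labeling and clustering with the same seed and initialization, and
reports the fraction of patients keeping their priority-group label and
their cluster. Perturbed and baseline clusterings are index-matched with
the Hungarian algorithm before comparison so the retained fraction is
well-defined under label switching. Note that in the default pipeline the
cluster geometry is the alpha matrix, which does not involve the weights,
so cluster stability is 1.0 by construction and the informative number is
label stability; `cluster_on="weighted_alpha"` clusters `w_i·α_ip` instead,
propagating the perturbation into the cluster geometry.

## Stratification

Two geometries are offered, because centroid-based K-means is not defined
on a Gower dissimilarity:

* `euclidean` (default): Lloyd's K-means on the alpha profiles, which are
  all numeric on a common [0, 1] scale. k-means++ seeding, 10 restarts,
  convergence at squared-center-shift ≤ 1e-6, empty clusters re-seeded at
  the point farthest from its center. The within-cluster sum of squares is
  recorded after every assignment step (`objective_path_`) and is
  non-increasing; tests verify the path and check the final optimum against
  exhaustive enumeration on 6-point instances and against scikit-learn's
  KMeans on larger ones.
* `gower`: PAM (BUILD + SWAP) k-medoids on the Gower matrix of the
  mixed-type raw cohort. Gower contributions are range-scaled absolute
  differences for numeric variables (the declared domain width for registry
  continuous variables, which is stable across cohorts; the observed range
  for plain numeric input), rank-normalized absolute differences for
  ordinal, and mismatch indicators for categorical/binary. Zero-range
  numeric variables contribute 0 and are flagged.

K is selected by mean silhouette over a candidate range (silhouette
computed in the same geometry as the clustering), with the objective curve
reported for elbow inspection; K = 3 also carries the clinical meaning of
three priority tiers. Clusters are ranked by mean member score into
High/Medium/Low (ordinal labels P1..PK for other K; ties broken by the
higher maximum member score, with a warning). PCA runs on centered,
unscaled alpha — entries already share a scale — with the sign convention
that each component's largest-magnitude loading is positive.

Cluster separation is tested by permutation: the statistic is the Wilks'-
lambda-style ratio det(W)/det(W+B) of within to total scatter, the null is
generated by label shuffles, and p = (1 + #{permuted ≤ observed}) / (1 + B).
The permutation form avoids the multivariate-normality and sample-size
assumptions of the F-approximation, which matter at toy-fixture sizes.
Mahalanobis distances between centroids use the pooled within-cluster
covariance with a 1e-8 ridge; a still-singular covariance raises an error
naming the deficient columns.

## Priority labels

Three labeling rules: empirical tertiles of the score distribution
(boundaries at the 1/3 and 2/3 quantiles with linear interpolation,
boundary scores going to the higher-priority group, favoring earlier care);
fixed operational thresholds (High strictly above 0.29, Low strictly below
0.18, boundary values Medium — the strict reading of "greater than" /
"below"); and cluster-derived labels as above. The 0.29/0.18 defaults are
the operational thresholds adopted in the reference ENT setting and are
plain parameters.

## Simulator

State per patient: list-entry day (non-positive values mean the patient is
already on the list at simulation start carrying accrued wait — the
standing-backlog reading used for a prevalent waiting list), operated flag,
at most one urgent admission. Per simulated day:

1. up to `capacity` listed patients are operated — chronological policy:
   ascending entry day (ties by position); prioritized: descending score
   (ties by entry day). Patients with an urgent admission are escalated to
   the head of the queue (configurable);
2. each still-waiting, never-admitted patient draws risk
   `min(Gamma(α₀ + δ·e^{λt}, rate β₀), 10)` at elapsed wait `t` and is
   urgently admitted with probability `1/(1+exp(−(γR−θ)))`; admissions draw
   Poisson(λ_D) bed days.

Defaults: γ = 1.8, θ = 4.5 and λ_D = 3.8 days (the calibrated values of
the reference setting); α₀ = 2.0, β₀ = 1.0, δ = 0.5, λ = 0.05/day, chosen
so the expected risk starts near 2 on entry to the backlog and saturates
near the cap within about two months, consistent with a near-cap mean exit
risk under chronological scheduling of a long-standing backlog; horizon
180 days; capacity 2/day; 1000 Monte-Carlo replicates. The Gamma shape is
internally capped at 1e9 (any larger shape puts all mass far above the
risk cap anyway) to keep `exp` finite at extreme waits. All queue mechanics
beyond the three published model components — per-day capacity, the
single-admission rule, escalation, per-day hospitalization checks,
censoring at the horizon — are this package's contract and are
configurable, since no standard convention exists.

Indicators per replicate: mean risk at exit (surgery day, or horizon for
censored patients — the "risk at decision time" read-out), % of patients
with ≥ 1 urgent admission, mean urgent bed days per *hospitalized* patient
(the convention under which the baseline value equals λ_D), and mean wait
of the High-priority group under whichever labeling is supplied. Replicate
seeds are spawned from the master seed; by default both policy arms of a
replicate share one stream (common random numbers) so policy differences
are not drowned in demand noise; set `common_random_numbers=False` for
independent arms. Confidence intervals are 95 % percentile intervals
(2.5/97.5 empirical quantiles) across replicates.

## Synthetic data

The generator emulates the reference study conditions: 205 patients, 20
registry variables, 7 raters, three equal-prevalence latent severity
groups, rater noise SD 1, and two group-independent binary demographics.
Ratings are a latent uniform-[0,10] consensus per variable plus clipped
Gaussian rater noise. Cohort values are drawn per variable from a softmax
over the variable's impact shares, `p(level) ∝ exp(b_g · α_level)`, with
the Medium group at the unshifted distribution and the High/Low sharpness
`b_g` solved (Brent's method) so the mean normalized value moves up/down by
`effect_size` (default 0.25) relative to Medium — clipped at the feasible
extreme with a warning when a variable's share span is narrower than the
requested gap, as is common at 0.25. This is the simplest mechanism that
guarantees strictly ordered High > Medium > Low mean profiles in every
variable; a consequence worth knowing is that clipped variables make the
High/Low groups nearly deterministic while Medium stays maximally
dispersed, so on individual seeds a few Medium patients genuinely resemble
Low/High ones and cluster recovery (expected ARI ≈ 0.95) occasionally dips
just below 0.9 for a single cohort. Missingness is completely at random —
the imputation remedy, not the missingness mechanism, is the modeled
object. Entry dates are uniform over a 365-day listing window.

What the generator does *not* emulate: the real cohort's marginal
distributions and inter-variable correlations (not published), informative
missingness, rater-specific biases, or time trends in arrivals. Passing
tests therefore demonstrate the correctness and internal coherence of the
pipeline under a controlled latent-group model, not its clinical
performance on real ENT data.

## Fairness audit

Demographic parity is tested as independence of the priority-label ×
attribute contingency table: chi-square when every expected count is ≥ 5,
otherwise a Monte-Carlo permutation null of the same statistic. A constant
attribute trivially satisfies parity (p = 1, flagged). Several attributes
audited together are Holm-adjusted. No equalized-odds or counterfactual
machinery is attempted — the audit asks only whether label rates differ by
attribute.

## Problem sizes and determinism

Default test and acceptance runs use the generator's native cohort size
(205) with 50-seed replication for recovery properties, 10³ replicates for
calibration checks, and 10⁵ draws for closed-form Monte-Carlo comparisons
(3-standard-error tolerances). All stochastic components take explicit
seeds; replicate streams derive from `numpy` `SeedSequence` spawning, so
every reported quantity is bit-reproducible for a fixed master seed.

## Known limitations

* Expert impact scores in the default registry are package defaults, not
  elicited values; real deployments must supply their own registry.
* The simulator's risk-growth constants are free parameters; absolute
  simulated outcome levels are scenario-dependent and only *contrasts*
  between policies under a shared scenario are meaningful.
* With the default per-day hospitalization checks and the reference
  logistic calibration, a long-waiting backlog experiences near-universal
  urgent admission; the admission *rate* indicator is informative mainly
  under milder calibrations or shorter accrued waits.
* K-means assumes roughly spherical groups on the alpha scale; strongly
  non-spherical populations would need the Gower/k-medoids mode or methods
  outside this package's scope.
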