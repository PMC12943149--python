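# Methods

This note documents the models, numerical choices and limitations of
`tdp`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Hourly profiles

The analysis object is a 24-bin vector of hourly proportions of daily
energy.  Main meals are mapped to standard windows — breakfast bins
{6,7,8}, lunch {11,12,13}, dinner {17,18,19} — with the meal's energy
spread uniformly over the three bins, regardless of the reported clock
time; snacks are assigned wholly to `floor(reported time / 60)`.
Uniform within-window spreading is the minimal-assumption choice; a
single-bin placement would make the window-width choice decisive, and
both the window bins and the spreading rule are module constants that a
caller can override.  Profiles are normalized by total daily energy, so
clustering sees only the relative temporal distribution.  Chrono
indicators (first/last eating occasion, eating window, midpoint,
skipping flags, morning 04:00–10:59 / daytime 11:00–16:59 / evening
17:00–03:59 energy shares) use the *reported* times of all occasions,
including main meals: standardizing them there would collapse the
eating-window distribution to a constant.

The exclusion cascade runs in a fixed order (age < 65 → no recall →
implausible energy → missing frailty inputs) and logs the count removed
at each step, so retained + removals always reconciles with the input
count.  The energy plausibility bounds (< 500 kcal, or > 5000 kcal for
women / > 6000 kcal for men) are strict inequalities: a person at
exactly 500 kcal is retained.

## DTW, kernel and kernel k-means

`dtw_distance` is the standard dynamic program with squared pointwise
cost and moves {match, insert, delete}; the reported distance is the
square root of the accumulated cost, so it coincides with Euclidean
distance for already-aligned sequences.  The test suite checks it
against exhaustive enumeration of all monotone warping paths.

**Band.**  The generic functions are unbanded by default, but the
*analysis pipeline* applies a Sakoe–Chiba band of radius 3 hours.  This
was a deliberate design revision: on sparse hourly profiles, unbanded
DTW warps across long zero runs almost for free, so a
breakfast-plus-lunch day aligns with a lunch-plus-dinner day at nearly
zero cost and meal identity is erased — empirically, two-meal eaters
from different archetypes collapsed into one cluster.  A 3-hour radius
retains the intended flexibility (a late lunch still matches an early
lunch) while keeping morning energy distinct from evening energy.  The
band is exposed everywhere (`band=None` restores unbanded DTW).

The kernel is Gaussian, `k_ij = exp(-d_ij²/(2σ²))`, with σ defaulting to
the median off-diagonal distance (median heuristic).  A Gaussian of a
DTW distance is not guaranteed positive semidefinite, so the kernel is
eigendecomposed and negative eigenvalues clipped to zero by default
(`psd_repaired` records whether clipping occurred); on a PSD kernel the
kernel k-means objective is provably non-increasing, and the
implementation asserts this every iteration.  Kernel k-means uses the
kernel trick for point-to-centroid distances, kernel k-means++
initialization, lowest-index tie-breaking, empty-cluster repair by
reseeding with the point farthest from its centroid, and the best of 20
seeded restarts (fully deterministic given the seed).  Medoids — the
members minimizing total within-cluster DTW distance — summarize each
cluster for the validity indices.

## Validity indices and consensus

Silhouette and Dunn are computed directly from the distance matrix;
Davies–Bouldin, its modified variant DB* (max scatter sum over *min*
medoid separation) and a pseudo Calinski–Harabasz use medoids in place
of centroids, the standard adaptation when only pairwise distances
exist.  Candidates K = 2…7 are ranked per index (rank 1 best, average
ranks on ties, undefined values imputed at the worst rank so a
degenerate candidate cannot win) and the rank sums aggregated; the
smallest K wins ties.  Consensus is invariant to any strictly monotone
transform of an index because only ranks enter.

A known behaviour, visible in the tests: on *very* clean mixtures the
lower-is-better indices keep improving as K grows past the truth,
because peeling a tiny satellite cluster always reduces scatter.  With
realistic within-cluster noise the consensus is driven by the real
structure; with the generator's behavioural noise fully enabled the
selection rate of the planted K is below the near-certain rate seen
under the archetype-shape condition (see "generator" below).

## Frailty, HEI and covariates

The five Fried criteria are scored exactly at their published cutoffs:
weight loss ≥ 3 kg; weakness = best grip of up to three trials strictly
below 28 kg (men) / 18 kg (women); exhaustion = top stress category
only; slowness / low activity = EQ-5D mobility / usual-activities level
≥ 2.  Frail ⇔ ≥ 3 criteria.  All 2⁵ combinations are tested
exhaustively, and on synthetic cohorts re-scoring the raw fields
reproduces the generator's planted flag exactly.

The Healthy-Eating-Index machinery scores 12 components in three groups
(adequacy: linear from a zero anchor to a full-credit anchor;
moderation: reversed; balance: full credit inside a band, linear decay
outside).  The shipped anchor values are a **synthetic stand-in** —
the official Korean component standards are not public in a citable
table here — so absolute totals are only meaningful relative to a
user-supplied standards YAML; the *machinery* (saturation, floors,
interpolation, monotonicity) is what the tests pin down.  Physical
activity is categorized at < 600 / 600–2999 / ≥ 3000 MET-min/week;
sleep at ≤ 6 / 6–8 / ≥ 9 h.

## Survey inference

All estimators use Taylor linearization with the with-replacement
approximation: per-row score contributions are summed to PSU totals and
their covariance accumulated within strata with the `n_h/(n_h−1)`
factor; design df = #PSUs − #strata, and CIs use t on that df (a normal
option exists).  Singleton-PSU strata are centred at the grand mean with
a logged warning by default ("adjust"), or raise ("error").

The Rao–Scott test divides the Pearson X² on weighted proportions by
the mean generalized design effect of the cell proportions; the
simple-random-sampling reference variance is `p(1−p)/(n−1)` (the
with-replacement finite-sample form) so that under equal weights with
one PSU per row and a single stratum the statistic reduces *exactly* to
classical Pearson X².  Survey logistic regression is pseudo-ML
(weighted Newton iterations to a gradient tolerance, explicit errors on
separation or non-convergence) with sandwich covariance A⁻¹BA⁻¹.  With
equal weights and an independence design every estimator reduces to its
classical counterpart, and all point estimates are invariant to
rescaling all weights.

**Mediation** uses the product-of-coefficients decomposition on the
log-odds scale: survey-weighted linear models give the exposure→mediator
paths `a_k`, one survey logistic gives the mediator paths `b_k` and the
direct effect, and the total effect is *defined* as
`direct + Σ a_k·b_k`, so the decomposition identity is exact in every
fit and every bootstrap replicate.  No rare-outcome rescaling is
applied — a documented limitation: with a common outcome, log-odds
products are not collapsible into a marginal total effect.  The
bootstrap resamples PSUs with replacement within strata (`m_h = n_h`,
weights rescaled by `n_h/m_h`), refits everything per replicate, drops
non-converging replicates (hard error above 5%), and reports percentile
CIs; it is bit-reproducible given the seed.  `precheck()` reports
design-based tests of each `a_k` so a caller can demote a mediator with
a null exposure path to a plain covariate, and the proportion mediated
is flagged as a suppression ratio whenever direct and indirect effects
have opposite signs.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a
fixture.  Defaults: cluster mix (38.8, 17.8, 18.0, 15.2, 10.2)%;
per-cluster morning/daytime/evening energy shares and per-meal skipping
probabilities taken from the published cluster table; daily energy
log-normal by sex (medians ≈ 1900/1500 kcal, σ = 0.25 on the log scale);
a stratified design with 16 strata × 8 PSUs and log-normal weight
variation (CV 0.4).  Mediators are latent standard-normal scales:
`zE` (standardized log energy; shifted +0.17 in the evening cluster and
−0.21 in the morning–evening cluster) and `zH` (diet quality; −0.19 in
the morning–evening cluster), with the written HEI column equal to
`50 + 10·zH` clipped to [0, 100].  Frailty is Bernoulli from a logistic
model with per-cluster direct log-odds (0.45 evening, 0.36
morning–evening — the latter is the published direct effect, the former
chosen so the planted indirect effect −0.046 and proportion mediated
sit at the published magnitudes), −0.27 per SD of each mediator, and
small age/sex effects around an intercept of −2.  Raw frailty fields are
constructed *inversely*: the criteria count is drawn conditional on the
planted flag and the raw measurements placed on the correct side of
each cutoff, so phenotype scoring recovers the flag exactly.

Free choices the source table does not constrain, fixed once: meal
times uniform within their standard windows; the steady cluster's
defining afternoon snack carries 15% of daily energy at a consistent
hour (15:00–15:59) — carved out of its daytime share so the published
window totals still hold — while other clusters snack casually (3–4% of
energy, 20–30% probability, uniform waking hour); per-person meal
shares are Dirichlet around the cluster archetype with concentration 60.
An early design draw of the steady snack uniformly over two hours made
that cluster bimodal in profile space and inseparable from the balanced
cluster; a single archetypal snack hour is the deliberate fix.

The **low-noise condition** used by the clustering-recovery experiments
isolates the archetypal shapes: concentration 300, stochastic skipping
and casual snacking off (the steady snack stays).  Under it, recovery of
the planted labels and consensus selection of K = 5 are essentially
certain, which is what the recovery tests assert.  Under the *default*
condition the skip events create genuine submodes (e.g. the ~18%
breakfast-skippers of the evening cluster), so K = 6–7 solutions are
sometimes legitimately competitive and the consensus selection rate of
K = 5 is materially lower — a property of the data-generating process,
not of the estimator, and the reason recovery claims are made under the
low-noise condition only.

What the generator does **not** emulate: food-code-level composition,
day-to-day intake variation (one recall day per person), covariate–
cluster confounding (off by default so association tests isolate the
planted effects), item nonresponse, and any realistic weight
calibration.  Passing tests therefore demonstrate correctness of the
estimators under the stated design, not robustness to those real-data
features.

## Problem sizes

The test suite and acceptance script use n = 500 cohorts (seed grids of
10–20) for clustering recovery, n = 800 × 500 replicates for CI
coverage, and n = 4000 — the scale of the motivating study — for
association and mediation recovery with B = 500 bootstrap replicates;
these sizes give Monte-Carlo error comfortably inside the asserted
tolerances while keeping a full run in tens of seconds.
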