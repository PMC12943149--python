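# tdp — temporal dietary patterns and frailty

`tdp` is a Python package for studying *when* older adults eat, not just
what or how much.  Starting from single 24-hour dietary recalls it

1. reconstructs each person's within-day energy trajectory as a 24-bin
   vector of hourly proportions of daily energy (main meals standardized
   to breakfast 06–08 h, lunch 11–13 h, dinner 17–19 h; snacks at their
   reported hour),
2. clusters these trajectories with **kernel k-means on dynamic time
   warping (DTW) distances** — a Gaussian kernel
   `k(i,j) = exp(-d_DTW(i,j)² / 2σ²)` with median-heuristic bandwidth and
   eigenvalue-clipping PSD repair,
3. chooses the number of clusters K by **Borda-count consensus** over
   five internal validity indices (Silhouette, Dunn, Davies–Bouldin,
   modified Davies–Bouldin, pseudo Calinski–Harabasz, all evaluated in
   DTW space with medoids in place of centroids),
4. scores a **modified Fried frailty phenotype** (unintentional weight
   loss ≥ 3 kg, grip strength < 28/18 kg for men/women, exhaustion,
   EQ-5D-based slowness and low activity; ≥ 3 of 5 ⇒ frail),
5. runs **design-based inference** for stratified multistage surveys:
   Taylor-linearized means, first-order Rao–Scott χ² tests,
   pseudo-maximum-likelihood logistic regression with a sandwich
   covariance built from between-PSU variation within strata, and
6. estimates **survey-weighted parallel-mediator mediation** (product of
   coefficients on the log-odds scale, `indirect_k = a_k·b_k`,
   `total = direct + Σ indirect_k` by construction) with percentile
   bootstrap CIs from PSU resampling within strata.

Because the motivating national survey microdata cannot be
redistributed, the package ships a first-class **synthetic cohort
generator** that emulates it: five archetypal temporal patterns
(balanced / steady / midday / evening / morning–evening) with published
mixing proportions and meal-skipping rates, log-normal daily energy,
a stratified-cluster survey design, and a planted
exposure → mediator → frailty structure (evening pattern: higher energy
intake that *suppresses* part of its direct frailty risk;
morning–evening pattern: lower energy intake and poorer diet quality
that *mediate* part of its risk).  Every downstream stage is therefore
testable end-to-end with known ground truth.

## Worked example

```bash
tdp run-all --n 1000 --seed 1 --out work/
```

or equivalently in Python:

```python
from tdp.pipeline import run_all
res = run_all("work", n=1000, seed=1)
```

This generates a 1000-person synthetic cohort, applies the exclusion
cascade, builds profiles, scans K = 2…7 and prints/writes (abridged):

```
selected K: 5
   silhouette  davies_bouldin  calinski_harabasz  aggregate
K
2       0.288           1.722            235.758       29.0
3       0.309           1.421            286.967       19.0
4       0.369           1.031            388.501       12.0
5       0.380           0.954            451.787       10.0
6       0.332           1.156            421.390       13.0
7       0.284           1.162            396.444       22.0
```

The consensus table shows each candidate K with its index values and
Borda rank sum ("aggregate", lower is better): the five planted
archetypes are recovered.  The pipeline then scores frailty, fits the
Model 1–3 ladder of survey-weighted logistic regressions (Model 2 adds
sociodemographics and alcohol; Model 3 adds standardized energy and
diet-quality scores), and runs mediation for the highest-risk cluster:

```
Survey-weighted mediation (B=200, dropped=0)
  a[energy] = -0.2667 (p=0.0094)  [-0.4481, -0.0625]
  b[energy] = -0.3013  [-0.5504, -0.0976]
  indirect[energy] =  0.0804  [ 0.0120,  0.2021]
  a[hei] = -0.1819 (p=0.0930)  [-0.3848,  0.0007]
  b[hei] = -0.3105  [-0.6057, -0.1152]
  indirect[hei] =  0.0565  [-0.0051,  0.1602]
  total indirect =  0.1368  [ 0.0403,  0.3052]
  direct = -0.0122  [-0.5308,  0.4765]
  total =  0.1246  [-0.4628,  0.6106]
```

Reading: membership in the morning–evening-type cluster lowers
standardized (log) energy intake by 0.27 SD (path *a*); each SD of
energy lowers the log-odds of frailty by 0.30 (path *b*); their product
is the indirect effect through energy, `0.08 [0.01, 0.20]`, with a
parallel path through diet quality.  Brackets are percentile bootstrap
95% CIs from 200 design-consistent PSU resamples.  Cluster-level odds
ratios at n = 1000 are individually noisy (the planted effects are
moderate); the planted structure is recovered precisely at the study
scale of n ≈ 4000 (see below).

Each stage is also exposed separately (`tdp generate`, `tdp trajectory`,
`tdp cluster`, `tdp select-k`, `tdp phenotype`, `tdp associate`,
`tdp mediate`) and as plain library functions.

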