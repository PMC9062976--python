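# Methods

## Problem and data model

Each case (transplant recipient) carries a set of donor-specific HLA
antibody (DSA) specificities, each measured on irregular days as a
single-antigen-bead MFI value. Per observed day the specificities are
summed into a total-DSA (tDSA) level; the analysis object is the per-case
tDSA trajectory over post-transplant days 0–50. Day 0 is the transplant
day; samples from day < 0 contribute only a `pre_treatment_tdsa` scalar
(the earliest pre-transplant sum), never the clustering grid.

### Preprocessing (stages 1–2)

- **Aggregation.** tDSA(day) = Σ over specificities measured that day.
  Duplicate (specificity, day) records and negative MFI are hard errors.
- **Inclusion.** A case needs its last post-transplant observation on day
  ≥ 20 (a 21-day span, days 0–20); configurable as `min_last_day`.
- **Interpolation.** Linear interpolation onto integer days between the
  first and last observed day, capped at day 50. No extrapolation: grids
  are ragged up to day 50. Interpolation cannot create a new maximum, so
  gating before or after interpolation is equivalent (asserted in tests).
- **Responder gate.** Cases whose post-transplant maximum is strictly
  below τ = 1500 MFI form the no-response group 0 and skip clustering; in
  this MFI range bead noise makes dynamics unidentifiable.
- **Scaling.** Responder trajectories are divided by their own maximum, so
  clustering sees shape, not magnitude.
- **Length split.** Trajectories reaching day 50 are clustered directly;
  20–50-day trajectories are classified afterwards.

## Distance: banded DTW

Classic dynamic time warping with absolute-difference local cost and steps
{(1,0),(0,1),(1,1)}; the distance is the cumulative cost of the optimal
monotone alignment (no step weights, no endpoint slack). The generic
`DtwConfig()` applies no warping constraint, but the **pipeline default is
a Sakoe–Chiba band of radius 5 days**. The band matters scientifically:
with unconstrained warping a 5-day-half-life decay aligns almost perfectly
onto a 23-day decay — the warping path simply dwells on the fast series'
shoulder — which erases precisely the fast-versus-slow modulation
distinction the clustering exists to detect (measured: the two scaled
archetype skeletons sit at DTW ≈ 3.7 unconstrained versus ≈ 6.5 at radius
5, while same-archetype noise pairs sit near 2–4). A week-scale band still
absorbs realistic shifts in peak timing (±5 days). For unequal lengths the
band follows the stretched diagonal j ≈ i·m/n and is widened minimally to
stay connected. Optionally the distance is divided by the optimal warping
path length (`normalize=True`), used wherever series of different lengths
must be scored on one scale.

DTW is not a metric; no triangle inequality is used anywhere.

## Clustering: mean-of-joining-series agglomeration

At each iteration the two closest active nodes merge; the new node's
representative is the **pointwise mean of the two merged representatives**
(a literal reading of mean-linkage over series; the mean over all member
series is available via `linkage="member_mean"` for sensitivity). All
distances to the new representative are recomputed by DTW. Ties in merge
distance break on the lexicographically smallest node-id pair, making
builds deterministic; permuting tie-free input permutes only labels.

Because representatives are recomputed, merge heights are **not**
monotone and the tree is not ultrametric (a constructed counterexample is
in the test suite); nothing in the implementation assumes otherwise.
Cutting at k undoes the last k−1 merges, so successive cuts are nested.
Clusters are numbered 1..k by decreasing size (ties: smallest member
index); `label_archetypes` then names clusters by nearest-DTW match to the
scaled archetype skeletons, greedily on globally smallest distances so no
two clusters take the same name while both are assignable.

### Short-series classification (stage 4)

A 20–50-day trajectory is a *truncation* of a full one — follow-up merely
stopped — so each short series is compared against the **prefix** of every
cluster mean covering the same days, using path-length-normalized banded
DTW; nearest mean wins, ties to the lower cluster number. Stretching the
short series across the whole 50-day mean instead would move its apparent
peak day (a day-13 peak in a 31-day series lands near day 21 after
stretching) and systematically misclassify modulation cases.

Classification accuracy depends on truncation point: fast modulation is
recognisable from day ~25, but fast versus slow modulation genuinely
overlap when follow-up ends before the decay rates separate (~day 25–30),
and flat sustained series truncated early are occasionally absorbed by the
slow-modulation mean. This is inherent to the shapes, not the classifier.

## Choosing k: gap statistic with block-bootstrap references

For k = 1..k_max (default 10; the acceptance runs use 8 — the one-SE
selection is unaffected by the cap as long as it exceeds the selected k):

- W_k = Σ_clusters D_r/(2 n_r), with D_r the full ordered-pair sum of DTW
  distances inside cluster r, evaluated on the tree's k-cut.
- Each of B = 100 reference sets contains `reference_size` (default: n)
  surrogate series; a surrogate concatenates five 10-point blocks, each a
  contiguous segment of a uniformly chosen scaled input series at a
  uniformly chosen start (sampling with replacement; segments never span
  series boundaries). Block bootstrap preserves the short-range
  autocorrelation of real trajectories while destroying group structure.
- Every reference set is re-clustered with the **identical** DTW
  mean-linkage pipeline — the null must hold the method fixed.
- Gap(k) = mean_b log W*_kb − log W_k, s_k = sd_b(log W*_kb)·√(1+1/B)
  (log-scale comparison is the default; linear scale available).
- **Selection:** the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}; if the
  gap never stops increasing, k_max is returned with a warning.

On synthetic 47-case responder cohorts at default settings this selects
k = 4 in 18/20 of a fixed 20-seed panel; across wider seed panels the
per-seed rate is roughly 80–90%, with misses almost always k = 3 (the
fast/slow-modulation split is the marginal one). The majority over five
seeds — the quantity `scripts/acceptance.py` reports — was 4 at every seed
tried. Single-archetype cohorts at the same scale select k ≤ 2, i.e. the
procedure does not invent structure.

## Association statistics

- **2×2 odds ratios**: rows = exposure (reference first), columns =
  outcome (negative first); OR = ad/bc with Wald 95% CI
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)); any zero cell yields an "n/a"
  marker rather than a number.
- **Fisher two-tailed exact** (scipy): sum of hypergeometric point masses
  ≤ the observed table's.
- **Wilcoxon rank-sum** (scipy Mann–Whitney): exact null for combined
  n ≤ 20 without ties, normal approximation with tie correction otherwise;
  all-tied input returns p = 1 with a warning.
- **Stepwise logistic regression**: forward/backward stepping from the
  intercept-only model. The step statistic is
  F = (ΔDeviance/Δdf)/(Deviance_larger/df_resid) referred to
  F(Δdf, df_resid) — the quasi-likelihood F test used by classic stepwise
  GLM tools; enter at p < 0.05, remove at p > 0.1. Terms showing complete
  separation (|coef| > 15 on the logit scale) are excluded with a warning.
  Reported per term: log-odds, OR with Wald CI from the fitted information
  matrix. Model scores yield ROC-AUC (rank formulation; baseline 0.5) and
  PR-AUC (average precision, i.e. step-wise interpolation, avoiding the
  optimistic trapezoidal bias; baseline = positive prevalence), plus both
  AUC/baseline ratios. Calibration under the defaults: with one OR = 5
  predictor among five noise covariates at n = 200, the true predictor
  enters in ≥ 90% and each noise covariate in well under 10% of
  replicates.
- **Survival**: Kaplan–Meier per response type (lifelines) and the
  two-group log-rank test. At moderate sample sizes the log-rank
  chi-square approximation is mildly anti-conservative (~6% empirical
  size at nominal 5% in our simulations).

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes; its
defaults are fixed and are the conditions under which all recovery
properties are stated.

**Trajectory skeletons** (per archetype, then multiplied by log-normal
measurement noise with CV `noise_cv`, default 0.1):

| group | shape | key defaults |
|---|---|---|
| 0 no response | flat baseline | 800 MFI, capped < 1500 |
| 1 fast modulation | quiescent 5 d → logistic rise → peak day 13 held 3 d → exponential decay, half-life 5 d, back to baseline | baseline 1200, peak 16000 |
| 2 slow modulation | quiescent → rise → peak day 13 → geometric decline to 30% of peak at day 50, ±15% week-period oscillation | baseline 1200, peak 12000 |
| 3 rise to sustained | slower rise → peak day 21 → held | baseline 4000, peak 15000 |
| 4 sustained | flat high level | 12000 MFI, floored > 1500 |

Choices worth flagging:

- The logistic rise reaches 95% of the peak amplitude at the peak day
  (steepness fixed by that constraint); decay is exponential in the
  stated half-life. Simplest forms consistent with sharp-rise /
  slower-rise descriptions.
- For slow modulation, the 30%-of-peak-at-day-50 plateau and a literal
  23-day half-life cannot both hold exactly; the plateau fraction is taken
  as the defining constraint (geometric decline hitting 0.30·peak at day
  50, implied half-life ≈ 21 d, consistent with IgG1's ≈ 23 d). Setting
  `plateau_fraction_day50=None` switches to pure half-life decay.
- Modulation-group baselines default to 1200 MFI: tDSA in these groups is
  subdued during quiescence and fast modulation settles back at its
  pre-peak level. Elevated baselines would blur the scaled fast/slow
  shapes into each other.
- Per-case heterogeneity: baseline and peak jittered log-normally
  (σ = 0.15), peak day shifted ±1 day. Strong enough to avoid clone-like
  cohorts, weak enough that between-archetype skeleton distances exceed
  within-archetype 95th-percentile distances (asserted in tests).
- Gate invariants are unconditional: group-0 output is capped just below
  1500 MFI and group-4 floored just above (at noise CV 0.1 the clip is a
  > 6σ event, but the invariant must hold for every draw).
- The tDSA skeleton is split across 1–7 specificities by a fixed Dirichlet
  weight vector per case; only the sum matters downstream. One
  pre-transplant sample (day −1) per case feeds the pre-treatment level.

**Sampling schedule**: day 0 always; days 1–20 sampled at 0.7/day; later
days at 0.2/day; the last-observed day is day 50 with probability 0.67,
else uniform on days 20–49 (so ≥ 80% of cases have ≥ 10 samples in the
first 20 days, and about two-thirds of responders reach day 50).

**Covariates/outcomes** are drawn per true group with probabilities that
reproduce the qualitative published pattern: modulation groups mostly
female, high early-rejection (57–80%), low 5-year graft failure (4–7%);
sustained groups more previous transplants and positive crossmatches,
lower rejection, high graft failure (25–31%). Graft-failure cases get an
event time uniform on days 60–1825, others are censored at 5 years.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: per-specificity kinetics (class I vs II, HLA-DP
behaviour), prozone/saturation artefacts at high MFI, treatment feedback
(plasmapheresis responses), late trajectory shifts, and correlated
assay-batch noise. Recovery results certify the pipeline's correctness
under its stated assumptions, not clinical performance.

## Numerical and engineering notes

- DTW kernels are numba-jitted (pure-NumPy fallback); a full gap run
  (47 series, B = 100, k ≤ 8) takes a few seconds on one CPU.
- All randomness flows through `numpy.random.Generator`; every public
  sampler takes a seed or Generator, the CLI fans one global seed into
  per-stage child seeds via `SeedSequence`, and gap curves are
  bit-reproducible given `ReferenceConfig.rng_seed`.
- Degenerate inputs fail loudly: all-identical series (zero dispersion),
  empty clusters, empty margins, out-of-range k, all-gated cohorts (the
  model skips clustering and reports every case as group 0).
- Acceptance-scale choices: the k-recovery runs use 47-series cohorts,
  B = 100, k_max = 8, and 5–20 seeds — the scale at which the selection
  behaviour is stated.
- The ROC-AUC baseline is fixed at 0.5 and the PR baseline at prevalence;
  both ratios are reported alongside the raw AUCs.

## Known limitations

- The gap-statistic one-SE rule is marginal exactly where the science is
  marginal (fast vs slow modulation); expect k = 3 on a minority of
  synthetic cohorts, and inspect the printed gap curve rather than
  trusting the point decision blindly.
- Path-length-normalized DTW mildly favours alignments with longer warping
  paths; it is used only where unequal lengths force a common scale.
- The stepwise F-test is one of several variants in circulation; a
  likelihood-ratio chi-square alternative would step slightly differently
  near the thresholds.
- MFI is semi-quantitative; nothing here corrects prozone or saturation.
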