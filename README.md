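# dsadyn

**Unsupervised classification of early post-transplant donor-specific
antibody (DSA) dynamics, and the outcome statistics that hang off it.**

After HLA-incompatible kidney transplantation, donor-specific antibody
levels (measured as single-antigen-bead MFI) are monitored intensively for
the first weeks. Summed per time point into a total-DSA (tDSA) level, each
patient traces a trajectory over the first 50 post-transplant days. These
trajectories fall into a small number of qualitatively different dynamic
responses — no response, fast modulation (sharp peak near day 13 with a
~5-day decay half-life), slow modulation (peak near day 13, slow decline to
~30% of peak by day 50), rise to sustained (peak near day 21, then
persistently high), and sustained (persistently above 1500 MFI) — and the
response type carries prognostic information: modulation dynamics go with
high early-rejection rates but excellent 5-year graft survival, sustained
dynamics with the reverse.

`dsadyn` implements the full analysis for transplant immunologists and
biostatisticians:

1. **Preprocessing** — per-day tDSA aggregation, linear interpolation onto a
   daily 0–50 grid, a 1500-MFI responder gate (group 0 = no response), and
   max-scaling of responder trajectories.
2. **Clustering** — dynamic-time-warping (DTW) distances d(x, y) under a
   Sakoe–Chiba band, agglomerative hierarchical clustering in which each
   merge's representative is the pointwise mean of the two joining series
   (distances to the new representative recomputed at every step).
3. **Model selection** — the gap statistic
   Gap(k) = (1/B) Σ_b log W*_kb − log W_k with
   W_k = Σ_r D_r/(2 n_r), where the B = 100 reference sets are block
   bootstraps (10-point segments) of the scaled series, re-clustered with
   the identical pipeline; k is the smallest value with
   Gap(k) ≥ Gap(k+1) − s_{k+1} (one-standard-error rule).
4. **Short-series classification** — 20–50-day trajectories are assigned to
   the nearest cluster mean by normalized DTW.
5. **Association statistics** — 2×2 odds ratios with Wald CIs, Fisher exact
   and Wilcoxon rank-sum tests, forward/backward stepwise logistic
   regression driven by an F test on deviance changes (enter p < 0.05,
   remove p > 0.1) with ROC-AUC and PR-AUC against their baselines, and
   Kaplan–Meier curves with a log-rank test for modulation versus sustained
   graft survival.

Because patient-level cohorts of this kind are not publicly shareable, the
package ships a first-class synthetic-cohort generator (`dsadyn.synth`)
that emulates the five trajectory archetypes, the early-dense sampling
schedule, and the covariate/outcome structure, so the entire pipeline is
reproducible and testable end to end.

## Worked example

```python
from dsadyn import DsaResponseModel
from dsadyn.synth import make_cohort

mfi, covariates = make_cohort([18, 15, 23, 16, 16], rng_seed=42)
results = DsaResponseModel(mfi, covariates).fit()
print(results.summary())
```

```
DSA dynamic-response model
================================================
cases: 88   selected k: 4

group  archetype           n
    0  no_response         18
    1  fast_modulation     15
    2  slow_modulation     21
    3  rise_to_sustained   18
    4  sustained           16

k    gap      s_k      one-SE criterion
1    +0.0265  0.0271   -0.7609
2    +0.8270  0.0397   -0.2522
3    +1.1285  0.0493   -0.3690
4    +1.5537  0.0562   +0.0449 <- selected
...

group  n   rejection_30d  gf_5y
    0  18        22.2%   22.2%
    1  15        93.3%    6.7%
    2  21        52.4%   14.3%
    3  18        66.7%   44.4%
    4  16        37.5%   31.2%
```

Reading the output: 18 cases never exceed 1500 MFI and are gated into the
no-response group; the remaining 70 are clustered (47 full-length series)
and classified (23 shorter series). The gap statistic's one-SE criterion
first turns positive at k = 4, so four dynamic clusters are kept, and the
nearest-skeleton labelling names them. The outcome table shows the
characteristic inversion: the fast-modulation group has the highest early
acute rejection rate (93%) but the lowest 5-year graft failure (7%), while
the sustained-type groups fail most (31–44%) despite rejecting less.

The same pipeline is scriptable from the shell:

```bash
dsadyn run-all --seed 42 --out-dir run/
dsadyn simulate --seed 1 --out-dir run/   # cohort CSVs only
dsadyn cluster --trajectories run/trajectories.csv --k auto --out-dir run/
```

Downstream, `results.km_modulation_vs_sustained()` returns the
Kaplan–Meier comparison, `results.modulation_vs_sustained_table("gf_5y")`
the 2×2 outcome table, and `dsadyn.assoc.stepwise_lr` the multivariable
model.

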