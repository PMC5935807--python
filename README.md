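# engagetraj

Functional clustering of daily log-in trajectories from eHealth
interventions, and association of the resulting trajectory groups with a
binary health outcome.

Web-delivered health programs (smoking-cessation websites, mental-health
apps, …) log every page opening, but the analysis-ready signal is much
simpler: did this participant use the program *at all* on each day of
follow-up? Reducing the log to a per-user binary series — day 1 = the
enrollment date, typically 365 days — turns "how do people engage over
time?" into a functional-data question. This package implements that
workflow end to end for biostatisticians and digital-health researchers:

1. **Ingest** — parse raw log-in events, align them to each user's
   enrollment date, and build the N × 365 binary engagement matrix
   (`engagetraj.io`).
2. **Presmooth + FPCA** — smooth each 0/1 series with a Nadaraya–Watson
   Epanechnikov kernel (default bandwidth 28 days) and decompose the sample
   of curves as

   ```
   X_i(t) ≈ μ(t) + Σ_k ξ_ik φ_k(t)
   ```

   with orthonormal eigenfunctions φ_k and per-user scores ξ_ik; the number
   of components K is the smallest reaching a fraction of variance explained
   ≥ 0.90 (`engagetraj.fpca`).
3. **Cluster** — group the score vectors with CLARA k-medoids (PAM on
   subsamples, best full-data medoid set kept), choosing the number of
   clusters by *prediction strength*: for candidate k, the minimum over test
   clusters of the fraction of co-clustered test pairs that a training-half
   clustering also co-assigns; the selected k is the largest candidate whose
   mean strength reaches the threshold (default 0.85)
   (`engagetraj.clustering`).
4. **Associate** — logistic regression of the outcome on trajectory-group
   indicators (reference = largest group) with bidirectional stepwise-AIC
   covariate adjustment, and baseline-category multinomial logistic
   regression of group membership on baseline characteristics, all reported
   as odds ratios with 95% Wald intervals (`engagetraj.association`).
5. **Report** — cluster proportions, per-cluster mean weekly log-in
   profiles, abstinence rates by cluster, OR tables, one-command pipeline
   with YAML config and a JSON run manifest (`engagetraj.report`, CLI
   `engage`).

Because trial log files are rarely shareable, `engagetraj.cohort` generates
synthetic cohorts with known truth: three engagement archetypes per arm
(week-level intensity profiles and mixing proportions transcribed from a
published two-arm smoking-cessation website trial), a week-12 assessment
spike, baseline covariates with trial-like marginals, and outcomes from a
configurable logistic model. Every stage of the pipeline is tested against
this generator.

## Worked example

```python
import numpy as np
import pandas as pd
from engagetraj import (simulate_cohort, presmooth, fit_fpca, prediction_strength,
                        clara, relabel_by_size, cluster_proportions,
                        abstinence_by_cluster, fit_logistic, odds_ratios, DesignSpec)

cohort = simulate_cohort("webquit", n_users=1240, seed=1)
smoothed = presmooth(cohort.matrix)                 # 28-day kernel smoother
model = fit_fpca(smoothed)                          # components to FVE >= 0.90
curve = prediction_strength(model.scores, k_max=5, seed=1)
print("prediction strength:", np.round(curve.ps_mean, 3), "-> k =", curve.selected_k)

result = relabel_by_size(clara(model.scores, curve.selected_k, seed=1))
print(cluster_proportions(result.labels))
print(abstinence_by_cluster(result.labels, cohort.outcome))

data = pd.DataFrame({"abstinent": cohort.outcome})
for g in (2, 3):
    data[f"cluster_{g}"] = (result.labels == g).astype(float)
fit = fit_logistic(DesignSpec("abstinent", ("cluster_2", "cluster_3")), data)
print(odds_ratios(fit).round(3))
```

Output:

```
prediction strength: [1.    1.    0.952 0.697 0.668] -> k = 3
 cluster   n  percent
       1 693    55.89
       2 379    30.56
       3 168    13.55
 cluster  abstinent  denominator  rate_pct
       1        132          603      21.9
       2         84          329      25.5
       3         53          145      36.6
     term  odds_ratio  ci_low  ci_high     p
cluster_2       1.223   0.894    1.675 0.208
cluster_3       2.056   1.393    3.034 0.000
```

Reading this: prediction strength stays at/above the 0.85 threshold through
k = 3 and collapses at k = 4, so three reproducible trajectory groups are
selected. After size-ordering, cluster 1 (55.9% of users) are the brief
users, cluster 3 (13.6%) the long-term users. Abstinence among responders
rises from 21.9% in the briefest group to 36.6% in the long-term group;
the unadjusted odds of abstinence for long-term vs brief users are 2.06
(95% CI 1.39–3.03). The cohort was generated with true group odds ratios of
1.42 and 2.00, so the fitted intervals cover the truth.

The same pipeline runs from the shell:

```sh
engage simulate --arm webquit --n 1240 --seed 1 --out scratch/cohort/
engage run --config examples/config.yaml --out scratch/run/
```

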