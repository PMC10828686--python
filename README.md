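# renalprog

CT-based survival prognosis for renal cell carcinoma (RCC), in two stages:

1. **Tumor grading.** A 3D MBConv (EfficientNet-style) classifier predicts
   the ISUP grade (1–4) of an RCC tumor from a two-channel input — the
   z-scored kidney CT crop and its binary tumor mask stacked on the channel
   axis. The flattened output of the adaptive average-pooling layer (2560
   values at full scale) is reused as a prognostic feature vector.
2. **Discrete-time survival.** A small network maps that feature vector to
   per-interval conditional survival probabilities on an equidistant time
   grid, trained with the discrete logistic-hazard likelihood. Because every
   interval gets its own hazard, the model is fully parametric yet
   non-proportional: each patient receives their own survival curve shape.

The package is aimed at researchers who have kidney CT volumes with
kidney/tumor segmentations plus follow-up data (death/censoring times) and
want personalized survival curves rather than a single proportional-hazards
risk score. A synthetic cohort generator (phantom volumes, grade-dependent
hazards, heavy censoring) makes every stage testable without any real data.

## The model

Follow-up `[0, t_max]` is split into `n` equidistant left-closed/right-open
intervals (default `n = 15`). With discrete hazard `h_i = P(die in interval
i | alive at its start)`, a patient dying in interval `j` has likelihood

```
L = h_j · ∏_{i<j} (1 − h_i)
```

and a censored patient contributes the product of `(1 − h_i)` over the
intervals they are known (by a midpoint convention) to have survived. The
network outputs `pred_i = 1 − h_i` through sigmoids; encoding each record as
indicator vectors `survs` (survived intervals) and `survf` (death interval)
turns the summed negative log-likelihood into the vectorized loss

```
L = −Σ_x Σ_i [ ln(1 + survs·(pred − 1)) + ln(1 − survf·pred) ]
```

The cumulative curve is `S(t_j) = ∏_{i≤j} pred_i`, linearly interpolated
between boundaries (constant event density within an interval). Evaluation
uses Harrell's C-index, the IPCW integrated Brier score on a 100-point
event-time grid, and the cumulative dynamic AUC.

## Worked example

```python
import numpy as np
from renalprog import synthetic, DiscreteTimeSurvival

cohort = synthetic.simulate_survival_dataset(synthetic.CohortConfig(seed=0))
feats = synthetic.simulate_feature_vectors(cohort.grade.to_numpy(), dim=20, seed=0)

model = DiscreteTimeSurvival(feats, cohort.duration_days.to_numpy(),
                             cohort.event.to_numpy(), n_intervals=15)
res = model.fit(seed=0)
print(res.summary())
curve = res.predict_curves(feats[:1], n_points=40)[0]
print(np.round(curve.cumulative, 3))
```

prints

```
Discrete-Time Survival Model (logistic hazard)
======================================================
No. patients:        244
  deaths / censored: 43 / 201
Feature dimension:   20
Time grid:           15 intervals of 199.1 days, horizon 2986 days
Network:             20 -> 32 (ReLU, BN, dropout) -> 15 (sigmoid)
Epochs run:          500
Best val. loss/pt:   1.1234
[0.917 0.89  0.827 0.794 0.759 0.734 0.688 0.571 0.532 0.485 0.446 0.378
 0.32  0.26  0.128]
```

— a synthetic cohort with the target cohort's shape (244 patients, ~13-18%
deaths under heavy censoring, ~3000-day horizon); the final vector is one
patient's predicted probability of still being alive at the end of each
200-day interval, non-increasing by construction.

The same pieces are reachable from a CLI
(`renalprog simulate|prepare|augment|train-grader|extract-features|`
`train-survival|predict-curves|evaluate|run-all`).

## Acceptance script

`scripts/acceptance.py` re-runs the full synthetic pipeline from scratch —
phantom generation, preparation, grading-network training, feature
extraction, survival fitting and the metric panel over three
event-stratified folds — at desk scale:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It prints the across-fold mean C-index, IBS and AUC for the run.
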