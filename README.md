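# brs-eeg

Task-induced **intra-subject variability** of resting-state EEG, measured as
a **between-run similarity (BRS)** of regional spectral-power vectors, with
the full analysis pipeline built around it: preprocessing, feature
extraction, classifier-based feature selection, and group statistics. The
intended users are clinical-neurophysiology researchers studying early
markers of cognitive impairment (mild cognitive impairment, MCI, and
Alzheimer's disease, AD, against healthy controls, HC) from two resting-state
runs recorded before and after a cognitively demanding task.

## The statistic

For one participant and one scalp region, each 6-s EEG epoch *i* of run
*r* ∈ {1, 2} yields a power vector **p**ᵢʳ ∈ ℝ⁷ whose components are the
region-averaged band powers of delta (1–4 Hz), theta (4–8), low alpha
(8–10), high alpha (10–13), low beta (13–20), high beta (20–30) and gamma
(30–45 Hz):

```
BPᵢʳ = (1/nₑ) Σⱼ BPᵢⱼʳ              (mean over the region's nₑ electrodes)
sᵢⱼ  = 1 / ‖pⱼ² − pᵢ¹‖              (reciprocal Euclidean distance)
S    = (1/(n·m)) Σᵢ Σⱼ sᵢⱼ          (mean over all n × m epoch pairs)
S̃(i) = (S(i) − mean_HC) / std_HC    (HC-benchmarked standardization)
```

High S means the two runs look alike (low intra-subject variability);
impaired groups are expected to fall below zero after HC standardization.
The package also implements the conventional single-run comparison features
(per-electrode spectral power, Katz's fractal dimension, band-limited
magnitude-squared coherence), LDA and RBF-SVM classifiers evaluated by
leave-one-participant-out cross-validation (LOPO-CV), a (C, γ) grid search
over powers of two, sequential forward selection (SFS) of the six regional
features, and Wilcoxon rank-sum group contrasts with Bonferroni control
(α/6 = 0.0083).

Because no public two-run clinical dataset accompanies this analysis, the
package ships a synthetic cohort generator (`brs_eeg.synthetic_cohort`)
that emulates the assumed structure at two fidelity levels — raw
multichannel time series, or regional power vectors directly — with a
group- and band-specific run-2 perturbation controlling the effect size.

## Worked example

```python
import numpy as np
from brs_eeg import (CohortSpec, simulate_power_vectors, brs_from_series,
                     feature_matrix, sfs_select, ParamGrid, compare_groups)

# 20 HC vs 20 MCI; the MCI-like group shifts its fast-band power
# (low/high beta, gamma) between runs by a factor e^±0.8
spec = CohortSpec(
    group_sizes={"HC": 20, "MCI": 20},
    perturbation={"HC": 0.05,
                  "MCI": {"low_beta": 0.8, "high_beta": 0.8, "gamma": 0.8}},
    seed=1,
)
cohort = simulate_power_vectors(spec, n_epochs=36)
results = brs_from_series(cohort.series, cohort.groups)

X, pids, labels, regions = feature_matrix(results)          # 40 x 6
mci = np.array([l == "MCI" for l in labels])
print("mean standardized BRS  MCI:", round(X[mci].mean(), 3),
      " HC:", round(X[~mci].mean(), 3))

trace = sfs_select(X, np.array(labels), "svm",
                   grid=ParamGrid.small(), feature_names=regions)
print("SFS+SVM LOPO-CV accuracy:", trace.best_score,
      "using", trace.best_feature_names, "at (C, γ) =", trace.params)
```

prints

```
mean standardized BRS  MCI: -1.572  HC: 0.0
SFS+SVM LOPO-CV accuracy: 1.0 using ('frontal', 'central', 'occipital', 'parietal') at (C, γ) = (0.125, 0.125)
```

i.e. the perturbed group sits about 1.6 HC standard deviations below the
healthy reference, and the jointly optimized feature subset and SVM
hyperparameters separate the two groups perfectly in LOPO-CV at this effect
size. `compare_groups(results, cohort.groups, [("MCI", "HC")])` then gives
the per-region rank-sum contrasts with the Bonferroni-corrected level.

A command-line interface mirrors the stages:

```bash
brs-eeg simulate --out cohort/ --groups HC=4,MCI=4 --seed 1
brs-eeg extract-brs --in cohort/ --out brs.csv
brs-eeg classify --brs brs.csv --task mci-hc --clf svm --out clf.json
brs-eeg stats --brs brs.csv --out stats.csv
```

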