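# ithrad

Habitat-radiomics quantification of **intratumoral heterogeneity (ITH)**
from CT lesions, and the survival machinery to turn it into a
**distant-metastasis (DM) risk model** — built for retroperitoneal
sarcoma imaging, applicable to any lesion with a grayscale image and a
binary segmentation.

Tumors with identical stage can behave very differently because their
tissue is not uniform: necrosis, dedifferentiated regions, and vascular
habitats coexist inside one mass and show up as spatial texture
structure on contrast-enhanced CT. `ithrad` makes that structure a
number. Each in-mask pixel gets a local radiomic signature; k-means
groups pixels into spatial *habitats*; and the dispersion of the
resulting label map is summarized by the ITH-score

```
ITH = 1 - (1/S_total) * Σ_i  S_i,max / n_i
```

where `n_i` is the number of connected regions of habitat `i`, `S_i,max`
the area of its largest region, and `S_total` the tumor area. A tumor
whose habitats form single blobs scores 0; fragmented, interdigitated
habitats push the score toward 1. Scores at k = 2..5 clusters are
concatenated into a feature vector for a random-forest DM classifier
(SMOTE-balanced, Bayesian-style sequential hyperparameter search), and
evaluated with the full survival battery: ROC AUC with DeLong
comparisons, Harrell's C-index, the integrated Brier score,
time-dependent AUC, calibration, decision curves, outcome-driven risk
cutoffs, and Kaplan-Meier/log-rank stratification.

Because the patient cohorts this method targets are not publicly
distributable, the package ships a first-class synthetic-data module:
textured tumor phantoms with *known* habitat structure (so ground-truth
ITH is available in closed form) and full cohorts with clinical
covariates and proportional-hazards survival outcomes. Every pipeline
stage is validated against that ground truth.

## Worked example

```python
import numpy as np, pandas as pd
from ithrad import (CohortSpec, generate_cohort, ith_feature_vector,
                    fit_rf_classifier, predict_risk, evaluate_model,
                    optimal_cutoff)

# a 200-subject synthetic cohort whose DM hazard loads on true ITH
cohort = generate_cohort(CohortSpec(n_subjects=200, beta_ith=1.5,
                                    seed=7, grid_shape=(32, 32)))
tab = cohort.table

# per-lesion integrated ITH vector (k = 2..5)
ith = pd.DataFrame.from_dict({
    s.subject_id: {f"ith_k{k}": v for k, v in
                   ith_feature_vector(s.image, s.mask, seed=1).per_k.items()}
    for s in cohort.subjects}, orient="index")

tr, va = np.arange(140), np.arange(140, 200)
y = tab["event"].to_numpy()
bundle = fit_rf_classifier(ith.iloc[tr], y[tr], folds=5,
                           search_budget=10, seed=0)
cut = optimal_cutoff(predict_risk(bundle, ith.iloc[tr]),
                     tab["time_months"].to_numpy()[tr], y[tr])
report = evaluate_model(predict_risk(bundle, ith.iloc[va]),
                        tab["time_months"].to_numpy()[va], y[va],
                        cutoff=cut)
```

Output for one fragmented-phenotype lesion and the fitted model:

```
S0006: true ITH 0.811, per-k scores {2: 0.299, 3: 0.353, 4: 0.422, 5: 0.387}
CV AUC (train): 0.661
validation AUC: 0.673   C-index: 0.631   IBS: 0.201
cutoff: 0.677   log-rank chi2: 24.5   p: 7.5e-07
```

Reading it: the lesion's habitats are shattered (ground truth 0.81) and
the computed per-k scores are correspondingly high for its cohort; the
risk model built *only* on the four ITH scores discriminates future DM
on held-out subjects (AUC 0.67 against a noisy binary endpoint), and
splitting validation subjects at the training-derived cutoff separates
their DM-free survival decisively (log-rank p ≈ 1e-6).

A thin CLI covers the shell workflow:

```bash
ithrad simulate --out cohort/ --n-subjects 50 --seed 1
ithrad ith --image cohort/S0000_image.nii.gz --mask cohort/S0000_mask.nii.gz \
           --seed 1 --out scores.csv --render map.png
ithrad evaluate --pred risk.csv --outcomes outcomes.csv --out report.json
```

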