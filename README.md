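# lcarisk

Latent-class stratification of competing-risk survival in cancer-registry
cohorts.

## The problem

Molecular subtypes of colorectal cancer stratify overall survival poorly
when many patients die of causes other than their cancer: other-cause
deaths act as competing risks, and a subtype enriched in frail patients
looks "high risk" for reasons unrelated to tumor biology.  When cause of
death is not recorded (as in most molecular cohorts), cause-specific
survival cannot be computed directly.

`lcarisk` implements an indirect route.  A latent class analysis (LCA) on
routinely available categorical indicators — age group at diagnosis, sex,
race/ethnicity, tumor site, stage — partitions patients into classes that
differ sharply in their *cause-specific* death hazards.  Adjusting survival
comparisons for this class structure then recovers much of the
cause-specific signal even without cause-of-death labels.

## The model

Latent class model for the indicators: with class prevalences π_c and
item-response probabilities ρ_jck (indicator j, class c, category k),

    P(Y_i) = Σ_c π_c Π_j ρ_{j,c,y_ij},

fitted by EM with random restarts; the number of classes is chosen by BIC
(AIC below n = 500) subject to normalized entropy ≥ 0.8, mean posterior per
class ≥ 0.5, smallest class > 5%, and optionally a parametric bootstrap
likelihood-ratio test of K vs K−1.

Competing-risks layer: Kaplan–Meier, the Aalen–Johansen cumulative
incidence estimator F_k(t) = Σ_{t_j≤t} S(t_j−) d_kj/n_j (the unbiased
reference), the naive KM complement that treats competing deaths as
censoring, and cause-specific proportional-hazards fits (the "multi-state
model" = the pair of cause-specific Cox fits, Efron ties).

Adjustment layer: per-patient rescaled weights
w = P(Z=z) / P(Z=z | G=g), renormalized so each comparison group keeps its
size; weighted KM curves; a robust score test (a log-rank test corrected
for weighting); and Harrell's C-index with pair weights w_i·w_j.  A
class-mixture CIF — stratified naive CIFs recombined at observed stratum
shares — quantifies how much of the competing-risk bias the class structure
absorbs.

A synthetic cohort generator reproduces the structure the analysis assumes
(latent classes with conditionally independent indicators, class-specific
exponential cause-specific hazards, optional confounded subtype labels) so
the whole pipeline is testable without registry access.  Its packaged
default uses the published 4-class solution for colorectal cancer:
π = (47.63, 30.76, 15.94, 5.67)%, the published item-response table, and
cause-specific hazard ratios (1, 1.20, 1.41, 1.12) for cancer death and
(1, 2.82, 0.72, 0.22) for other-cause death versus class 1.

## Worked example

```python
import numpy as np
from lcarisk import (
    default_config, simulate_cohort, scan_models, posterior, assign_classes,
    multi_state_model,
)

cohort = simulate_cohort(default_config(n_patients=10_000, seed=11))
scan = scan_models(cohort, range(1, 7), seed=0, n_restarts=10, tol=1e-8)
print("selected number of classes:", scan.selected_k)

params = scan.fits[scan.selected_k]
print("class prevalences (%):", np.round(100 * params.class_prevalence, 2))

assign = assign_classes(posterior(params, cohort), cutoff=0.5)
labels = assign.labels.astype(str)
msm = multi_state_model(cohort.time, cohort.event, labels, reference="1")
for cause, name in ((1, "cancer death"), (2, "other-cause death")):
    rows = msm[cause].table.query("~reference")
    print(f"{name}: " + ", ".join(
        f"class {r.level} HR {r.hr:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
        for r in rows.itertuples()))
```

prints

```
selected number of classes: 4
class prevalences (%): [49.51 29.68 15.45  5.36]
cancer death: class 2 HR 1.14 (1.04-1.25), class 3 HR 1.36 (1.24-1.50), class 4 HR 1.09 (0.93-1.28)
other-cause death: class 2 HR 2.56 (2.36-2.78), class 3 HR 0.76 (0.66-0.88), class 4 HR 0.30 (0.21-0.42)
```

The scan recovers the 4-class structure; the fitted prevalences sit within
sampling error of the generating (47.63, 30.76, 15.94, 5.67)%.  The
cause-specific fits on the *fitted* class labels show the expected pattern:
class 2 carries a 2.6-fold other-cause death hazard while class 4 is
protected (HR 0.30), and classes 3 and 4 carry the excess cancer-death
hazard — the signature that makes the classification useful for
cause-specific stratification.  (HRs estimated from fitted labels are
mildly attenuated relative to the generating values because of residual
classification error.)

The same workflow is available from the shell:

```sh
lcarisk simulate --config default --out cohort.csv --seed 11 --n 10000
lcarisk scan --cohort cohort.csv --k 1:6 --out scan.csv
lcarisk report --config pipeline.yaml --out results/
```

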