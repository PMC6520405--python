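# tphen

Immune-contexture feature mining and survival-linked patient stratification
for co-registered IHC cell maps.

`tphen` is aimed at computational-pathology groups running retrospective
biomarker-discovery studies on small immunotherapy cohorts: given per-patient
cell maps from serially sectioned, differently stained slides (e.g. CD3 and
CD8), tumor/exclusion annotations, and clinical outcomes (therapy response,
overall survival), it quantifies the immune contexture per tissue
compartment and searches for stratification rules that predict response —
while guarding against the overfitting that dominates at n ≈ 30 patients
with 100+ candidate features.

The pipeline:

1. **Co-registration** — chromogen-agnostic normalisation
   (`255 − min(R,G,B)`) and rigid NCC alignment of serial sections, exposed
   as a landmark-grid transform.
2. **Patch factory** — automatic training-data generation for a
   brown-stain-vs-melanin patch classifier by virtual multiplexing (brown
   objects on the red-chromogen FoxP3 section are melanin by construction),
   with rotation × histogram-scaling augmentation (exactly 15 extra variants
   per patch), class balancing, candidate-patch pre-selection and prediction
   heatmaps behind a pluggable classifier contract.
3. **ROI features** — six regions (tumor, stroma, tumor+stroma, TME bands of
   338/676 µm by dilation, ITI band of 676 µm by erosion) and 114 features
   per case: 12 melanin-corrected densities, 66 pairwise density ratios, 36
   cross-stain k-nearest-neighbour distances (k ∈ {2,4,8}).
4. **Stratifiers** — exhaustively optimised uni-variate cut points
   (accuracy or log-rank objective, minimum-class-size constraint),
   bi-variate logical combinations (AND/OR/XOR), CART trees with gini
   (`1 − Σₖ p²ₘₖ`) or cross-entropy (`−Σₖ pₘₖ log pₘₖ`) impurity, and
   scikit-learn-backed linear baselines.
5. **Selection engine** — four feature-selection strategies (whole-data,
   95%-subsample voting, leave-one-out, repeated inner cross validation)
   inside a nested Monte Carlo cross-validation harness (M = 50 outer runs ×
   N = 10 folds) with aggregated test-fold predictions, method comparison by
   t/Mann–Whitney/ANOVA, and a final refit on all data.
6. **Survival evaluation** — bespoke Kaplan–Meier and log-rank
   (cross-checked against lifelines), aggregated KM curves over all Monte
   Carlo runs, and stratification summaries in which an unreached median is
   reported as `"not reached"`, never a number.

Because studies like this rarely publish their whole-slide images, the
`synthetic` module generates full stand-in cohorts — co-registered CD3/CD8
point patterns on a shared tumor geometry with a planted CD8
intratumoral-enrichment effect and response-linked exponential survival — so
every downstream stage is testable end to end.

## Worked example

```python
import numpy as np
from tphen import (SimulationConfig, generate_cohort, clinical_frame,
                   RoiConfig, MccvConfig, SelectionConfig, run_mccv)
from tphen.roi_features import extract_feature_table
from tphen.selection_engine import selection_model_factory
from tphen.survival_eval import aggregate_km

cfg = SimulationConfig(seed=11, image_px=896, pixel_size_um=4.0)
cases, cellmaps, annotations = generate_cohort(cfg)          # 31 cases, 12 responders
clin = clinical_frame(cases)
X = extract_feature_table(cases, cellmaps, annotations,
                          RoiConfig(pixel_size_um=4.0))       # 31 x 114
res = run_mccv(X, clin.responder.to_numpy(),
               selection_model_factory(SelectionConfig(method="repeated_cv")),
               MccvConfig(M=10, N=10, seed=1), survival=clin)
print(f"mean aggregated test-fold accuracy: {np.nanmean(res.accuracies):.3f}")
agg = aggregate_km(res, clin)
print("median OS responder arm:", round(agg.arms["responder"].median, 1))
print("median OS non-responder arm:", round(agg.arms["non_responder"].median, 1))
```

prints

```
mean aggregated test-fold accuracy: 0.942
median OS responder arm: 33.2
median OS non-responder arm: 12.4
```

The planted effect separates the groups almost perfectly (the generator's
default effect size is strong by design; see `docs/methods.md`). The
predicted non-responder arm's pooled median overall survival lands on the
generator's 12-month class median; the responder arm's sits below the
40-month class median because the pooled arm absorbs the occasional
misclassified non-responder and censoring truncates the long tail.

A CLI mirrors the library for shell use:

```bash
tphen simulate --out cohort/ --seed 17
tphen features --cohort cohort/ --out features.csv
tphen mccv --features features.csv --clinical cohort/clinical.csv \
      --method repeated_cv --out mccv.json
tphen survival --predictions preds.csv --clinical cohort/clinical.csv \
      --out summary.json --plot km.png
tphen register --moving cd8.tif --fixed cd3.tif --out transform.json
```

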