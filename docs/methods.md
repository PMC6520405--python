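# Methods

`tphen` implements an image-based biomarker-discovery analysis for
immunotherapy response in malignant melanoma: from labeled cell maps of
co-registered serial IHC sections (CD3, CD8, with FoxP3 sections used only to
locate melanin), through region-of-interest partitioning and a 114-feature
immune-contexture extractor, to cut-point-based uni-, bi- and multi-variate
stratifier selection inside a nested Monte Carlo cross-validation (MCCV)
harness, evaluated with Kaplan–Meier survival statistics. Because the
whole-slide images such analyses consume are typically not shareable, a
synthetic-cohort module generates statistically structured stand-ins and is
itself first-class, tested code.

## Regions of interest

Six ROIs are derived from the pathologist-style tumor annotation by isotropic
morphological operations (Euclidean-disk structuring elements realised through
distance transforms, so margins are true physical distances):

| ROI | definition | default width |
|---|---|---|
| tumor | annotated tumor ∩ tissue | — |
| stroma | tissue ∖ tumor | — |
| tumor plus stroma | tumor ∪ stroma | — |
| TME small | dilation band outside the tumor border | 338 µm |
| TME large | dilation band outside the tumor border | 676 µm |
| ITI | erosion band inside the tumor border | 676 µm |

The margin widths follow the colorectal-cancer Immunoscore convention of an
invasive margin spanning a few hundred µm on either side of the tumor border.
Exclusion annotations (necrosis, artifacts) are removed from every mask.
*Stroma* deliberately includes the TME bands: the analysis opposes tumor to
all surrounding tissue, and the bands refine — rather than carve up — that
opposition. The tumor-core mask (tumor ∖ ITI) is produced for display and
sanity checks but carries no features. If the tumor is thinner than the ITI
width the core is empty and a warning is raised; the ITI then equals the
tumor, which is still a valid measurement region.

Across-section features use only the intersection of the co-registered tissue
masks, so a cell in one section is never related to tissue the other section
does not cover.

## Features (12 + 66 + 36 = 114)

* **Densities (12).** IHC-positive objects per ROI area, 2 stains × 6 ROIs.
  Areas are measured in prediction-heatmap pixels (80 × 80 px patches), the
  same unit in which melanin exclusion operates: any positive object lying in
  a patch the heatmap flags as melanin is removed from the count
  (whole-patch exclusion; sub-patch granularity would require the pixel-level
  segmentation the cell maps abstract away). A zero-area ROI yields a missing
  value, never zero; a stain with no positive objects at all is treated as a
  missing section, not a true zero.
* **Density ratios (66).** One per unordered pair of the 12 densities,
  emitted as a/b in a fixed canonical order. The lost direction is recovered
  downstream by the cut-point direction, since a/b > t ⇔ b/a < 1/t.
* **Cross-stain neighbour distances (36).** Mean distance (µm) from each
  ROI-restricted cell of one stain to its k nearest cells of the other stain
  (k ∈ {2, 4, 8}, both directions, six ROIs), with the other stain's cells
  first mapped through the rigid co-registration transform. Distances answer
  a different question from densities — co-occurrence rather than abundance —
  and k is varied because the relevant cluster size is unknown. If fewer than
  k neighbours exist, all are used and the value is flagged truncated.

Coordinates are 0-based with x = column; physical distances come from
`pixel_size_um`.

## Co-registration

Sections are normalised chromogen-agnostically (per pixel `255 − min(R,G,B)`,
so any stain becomes bright signal on dark background) and aligned rigidly:
candidate rotations are scanned, and for each the translation maximising the
normalised cross-correlation is found (FFT phase correlation proposes the
shift; the exact overlap NCC within a ±3 px window makes the final choice, so
the reported score is the true NCC of the overlapping tissue). For
whole-slide-scale inputs a coarse pass on ×16-decimated images bounds the
full-resolution refinement; small tiles search directly. The fitted transform
is exposed as a regular landmark grid (default spacing 512 px) so the
interface remains compatible with locally deforming registration schemes;
deformable refinement, multi-part tissue correspondence and torn/folded
sections are out of scope.

## Patch factory

Brown DAB chromogen and melanin are visually confusable. The factory labels
80 × 80 px patches (17.6 µm at 0.22 µm/px) of the CD3 section by virtual
multiplexing: brown objects on the co-registered FoxP3 section are melanin by
construction (the FoxP3 chromogen is red), so

* CD3-positive objects present and no transformed brown FoxP3 object →
  `cd3_pos`;
* transformed brown FoxP3 objects present and no CD3-positive cell →
  `melanin`;
* brown image content present but faint, and neither of the above →
  `nonspecific`.

Object presence uses the centroid rule (a patch owns an object iff the
centroid falls inside), which makes the three predicates pairwise disjoint
and label assignment order-independent. "Faint" is operationalised as mean
normalised-stain intensity of brown pixels below a configurable threshold
(default 80/255); nothing in the source analysis pins this number, so it is
exposed in `PatchSpec`.

Augmentation is the grid of four right-angle rotations × four linear
histogram scalings, one of which is the identity gain, giving exactly 15
additional variants per patch (16 combinations minus the duplicate of the
original). Default gains are (1.0, 0.8, 0.9, 1.2), clipped to [0, 255].
Balancing tops up each minority class by sampling without replacement from
its augmented pool until it reaches the majority count, warning when the pool
runs dry; the rule reaches exact balance whenever the pool suffices.

The patch classifier itself is a plug-in contract (`Patch → class name`); a
trained network is one valid plug-in, and the package ships a deterministic
rule-based reference classifier for end-to-end tests. Prediction heatmaps
have one pixel per patch (ceil division of the image extent), candidate
patches are exactly the tissue patches overlapping an IHC-positive object
(boundary objects select every touching patch), and non-candidates stay
`unprocessed`.

## Stratifiers

*Responder* (complete or partial response) is always the positive class.

* **Cut points.** Exhaustive scan of all midpoints between consecutive
  sorted unique feature values, both directions, under a minimum number of
  samples per *predicted* class (default 3 — the constraint's published
  existence is clear but its value is not, so it is configurable). Objective
  is either stratification accuracy or the log-rank p-value of the induced
  survival split; in the latter case the responder label goes to the arm
  with the better observed survival. Ties prefer the widest value gap, then
  the smaller threshold, then the `greater` direction — determinism matters
  more than the particular convention.
* **Bi-variate models.** Joint grid search over both thresholds, both
  directions and a logical combiner (AND, OR, XOR), maximising accuracy of
  the combined prediction, with the class-size constraint applied to the
  combined classes.
* **CART trees.** Greedy top-down induction with gini (`1 − Σ p²`) or
  cross-entropy (`−Σ p log p`, natural log — the base only rescales gains
  and never reorders splits) impurity; configuration is depth d ∈ {1,2,3},
  minimum node size s_min ∈ {5,8} and minimum leaf size l_min ∈ {3,5,6}.
  Splits with non-positive gain are rejected; equal-gain ties go to the
  earlier canonical feature, then the smaller threshold. Leaves record the
  class proportions p_mk, whose maximum is the prediction confidence. An
  exact-tie leaf majority goes to non-responder, the cohort's prior class.
* **Linear baselines.** Soft-margin SVM (hinge and squared hinge),
  perceptron and logistic regression through scikit-learn's `SGDClassifier`
  with feature standardisation — comparison baselines behind the same
  predict contract, not bespoke computation.

Missing feature values exclude a case from that feature's fit and yield a
missing prediction at apply time, never a silent default.

## Model selection and MCCV

The harness has three nested levels: an outer Monte Carlo loop (default
M = 50) randomly partitioning the cohort into N = 10 folds; an N-fold
cross-validation loop; and the innermost model-selection step, which only
ever sees its N−1 training folds. Test-fold predictions are aggregated per
run; the M per-run accuracies are the comparison currency between methods
(pairwise t and Mann–Whitney tests, one-way ANOVA across all methods).
Fold assignment is simple random without class stratification (a stratified
option exists but is off by default); fold sizes differ by at most one, and
every case is tested exactly once per run. One master seed spawns per-run
substreams (`numpy.random.SeedSequence`), so results reproduce end to end.

Uni-variate selection methods: best cut on the whole training set; repeated
95% subsampling without replacement (default 100 repetitions) with top-k
(k = 5) frequency voting; leave-one-out with aggregated held-out accuracy;
and inner_M-times repeated inner_N-fold cross validation (inner_N ∈ {5, 8})
with per-run top-k ranking and frequency voting, optionally with the
log-rank objective. For every method except whole-data the winner's
threshold is refit on the full training folds of the current MCCV fold —
training folds only, never the held-out fold, resolving an ambiguity in the
source description in the leakage-free direction. Frequency ties break by
higher mean accuracy, then canonical column order.

A leakage guard is part of the test suite: on pure-noise features and labels
the mean aggregated test-fold accuracy over M = 50 runs must not exceed the
majority rate by more than three standard errors.

The final model is refit on all cases; its training accuracy is reported but
explicitly labelled optimistic, as no cross validation is involved.

## Survival evaluation

The Kaplan–Meier product-limit estimator and the unweighted
(Mantel–Haenszel) two-group log-rank test are implemented directly on the
event tables and cross-checked against `lifelines` in the test suite. Tied
events and censorings at the same time follow the standard convention
(events first). A median the curve never reaches is a distinct
"not reached" state, never coerced to a number. Aggregated KM curves pool
every (case, run) pair by predicted arm — a case re-enters the pooled risk
set once per run — which matches the construction of aggregated test-fold
predictions; the pooled curves are descriptive, and any confidence band on
them would not be valid inference.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
histology:

* **Geometry.** One simply-connected tumor per case — a smooth random radial
  polygon (low-order cosine perturbations, ±8%) centred in the field — sized
  so all six ROIs are non-empty at the default widths. Defaults: 1664 px
  field at 2 µm/px (≈3.3 mm), tumor radius 800 µm.
* **Cells.** Inhomogeneous Poisson point patterns with constant intensity
  per compartment. CD8: stroma at `density_stroma` (default 60 cells/mm²),
  ITI at `ratio × density_stroma` where the per-case ratio is the group
  value (responders 6.0, non-responders 1.5) times unit-mean log-normal
  jitter (σ = 0.2), tumor core at half the ITI intensity. CD3 is 1.8× the
  CD8 stroma intensity with a fixed ITI enrichment of 2 in both groups — so
  only CD8 carries the planted effect, mirroring the direction of the
  best-performing published immune-contexture signatures (high CD8
  infiltration of the tumor relative to the surrounding tissue in
  responders). IHC-negative nuclei and melanin objects are uniform over
  tissue. The planted effect sizes are deliberately strong enough that the
  true ITI/stroma ratio separates the groups; the harness tests whether the
  *selection machinery* finds it against 100+ correlated and noise features,
  not whether a marginal effect is detectable at n = 31.
* **Registration.** The CD8 section lives in its own frame, offset from the
  CD3 frame by a known integer translation (±24 px) recorded as the per-case
  ground-truth transform.
* **Survival.** Exponential event times with class-specific medians
  (responders 40 months, non-responders 12 months — chosen to reproduce the
  qualitative separation of responder/non-responder curves, with the
  non-responder median near the reported ~10 months scale) and independent
  uniform censoring on a 1–59.5-month follow-up window applied to a
  configurable fraction of cases (default 0.3).

What the synthetic data does **not** emulate: staining variation, cell
morphology, segmentation errors, spatial clustering beyond compartment
boundaries, multiple tissue fragments, annotation noise, or any correlation
structure between features beyond that induced by the single planted effect.
A green suite therefore certifies the pipeline's statistical machinery and
bookkeeping, not performance on real slides.

## Problem sizes and numerical choices

Tests and the acceptance script run the cohort analyses on a coarsened
geometry (448 px at 8 µm, or 896 px at 4 µm) that preserves physical cell
counts and margin widths while keeping distance transforms fast; the package
default (2 µm) is what a real cell-map export would use. MCCV uses the
default M = 50, N = 10 everywhere; the planted-recovery experiment in the
acceptance script uses 20 harness repetitions (the test suite uses 50).
Floating-point ties in the cut-point scan are broken exactly (comparisons on
the computed values, no tolerance); impurity gains below 1e-12 are treated
as zero to avoid splitting on rounding noise.

## Known limitations

* Rigid-only registration; the landmark grid is the extension point for
  deformable schemes.
* Whole-patch melanin exclusion biases absolute densities downward when
  melanin is abundant (ratios are unaffected, as exclusion hits all
  compartments at the same rate under the uniform-melanin model).
* The bi-variate fitter's joint grid search is exhaustive and O(T²) in the
  number of candidate thresholds; it is meant for cohort-scale n, not
  thousands of samples.
* Aggregated KM pooling double-counts cases across runs by construction;
  medians are descriptive summaries of harness behaviour.
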