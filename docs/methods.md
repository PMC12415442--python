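# Methods

`luadgrade` implements the non-neural computational core of a quantitative
growth-pattern analysis pipeline for resectable lung adenocarcinoma (LUAD):
it starts where a pixel-wise pattern segmentation ends (an integer label
mask or a pattern-composition table) and carries the analysis through
composition quantification, grading, agreement statistics, segmentation
evaluation and survival-based validation.

## Pattern quantification and correction weights

Six architectural patterns are recognised: lepidic, acinar, papillary,
micropapillary, solid and complex glandular (cribriform / fused glands).
A `PatternCodebook` binds raster codes to pattern names (default 0 =
background, 1–6 in the order above) and carries two grade-tier maps:

* **tier 3** — lepidic → 1; acinar, papillary → 2; micropapillary, solid,
  complex glandular → 3 (the WHO/IASLC convention);
* **tier 4** — as tier 3 but complex glandular is split out as an
  intermediate grade 3, with micropapillary and solid at 4.

Pattern abundance is quantified at the pixel level. Because the epithelial
tumor component is systematically denser in high-grade patterns than in
lepidic areas, raw pixel areas are multiplied by pattern-specific
correction weights before percentages are formed (lepidic 1.41, acinar
1.35, papillary 1.06, micropapillary 1.14, solid 1.00, complex glandular
1.10; dimensionless multipliers derived from the segmentation tool's
training distribution). Weighting can be disabled (`apply_weights=False`)
for raw-percent mode. With a known scale, mm² = pixels × (mpp/1000)².

Case-level compositions pool **weighted areas** across slides before
percentages are recomputed (area-weighted pooling, not a mean of slide
percentages), so larger tumor areas dominate. The dominant pattern is the
percentage argmax with ties broken toward higher clinical severity
(default ascending order: lepidic < acinar < papillary < complex glandular
< micropapillary < solid — a conservative clinical tie-break, configurable).
The secondary pattern is the next most abundant one with ≥ 5% abundance
(the conventional reporting floor, configurable); when none qualifies the
Gleason convention applies (secondary := dominant, flagged as a proxy).

## Grading systems

All engines are pure functions of the case composition and record the rule
path taken (base grade, upgrade flag, high-grade percentage):

| system | rule |
|---|---|
| WHO | tier-3 grade of the dominant pattern only |
| IASLC | WHO base; G1/G2 upgraded to G3 when micropapillary + solid + complex glandular **> 20%** (strict inequality; 20% exactly does not upgrade) |
| simplified IASLC | as IASLC with complex glandular removed from the upgrade sum |
| modified IASLC | as IASLC with the threshold at 50% |
| four-tier | tier-4 grade of the dominant pattern |
| prognostic score | sum of tier-3 grades of dominant + secondary; score 3 split into 3a (1+2) and 3b (2+1); groups: 2 → PG0, 3a → PG1, 3b → PG2, 4 → PG3, 5 → PG4, 6 → PG5 |

The high-grade percentage sums the *weighted* percentages, consistent with
quantification. Scores 4 and 5 pool all tier combinations with that sum
(Gleason-sum semantics); only the score-3 split is asymmetric. PG0 (purely
lepidic, score 2) is emitted with a flag rather than dropped — it is rarely
relevant in routine diagnostics but must not silently disappear. A
four-tier scoring variant (`score_prognostic(..., tiers=4)`) returns the
raw (dominant, secondary, score) triple without a group mapping, since no
standard grouping exists for it.

`sweep_thresholds` re-grades a cohort under a grid of upgrade thresholds
and reports group sizes, the k-sample log-rank statistic and the
concordance index per threshold. At threshold 100 the IASLC rule
degenerates exactly to WHO grading; at 0 any high-grade presence upgrades.

## Agreement statistics

Cohen's kappa is computed from the contingency table as 1 − D_o/D_e with
disagreement weights: all-or-nothing (`weighting="none"`, classical kappa)
or equally spaced over a declared category order (`"equal"`, linear
weighted kappa). The category order defaults to the severity order;
patterns are nominal, so the weighted variant's meaning depends on this
declared order — both variants are always available and reported. When
both raters use a single shared category, the degenerate 0/0 is resolved
to kappa = 1 for perfect agreement. Pairs with a missing rating are
dropped.

Majority voting uses pathologist raters only — AI raters participate in
pairwise kappa but never in votes. Consensus requires the modal count to
reach `consensus_min` (default a strict majority, i.e. 7 of 13); modal
ties yield no consensus, with the tie broken toward higher severity for
reporting (mv1) and flagged. The leave-one-out analysis compares one
rater to the majority vote of the remaining raters (AI excluded),
restricted to items where the reduced panel reaches consensus; dropped
items are counted and reported.

## Segmentation evaluation

Per-class Dice = 2|GT_c ∩ PR_c| / (|GT_c| + |PR_c|), computed over pixels
whose ground truth is not the ignore code (evaluation is confined to the
annotated area). The "average Dice" is the unweighted (macro) mean over
classes present in the ground truth; a support-weighted mean is reported
alongside. The discrepancy matrix distributes, for each ground-truth
pattern, its misclassified pixels over the predicted classes in row
percentages (rows sum to 100 or are undefined when nothing was
misclassified); pixels predicted as background inside the annotated area
are tallied in a dedicated background column.

## Survival harness

`SurvivalRecord` holds endpoint (OS/CSS/PFS), follow-up time in months,
event indicator and the common clinicopathological covariates; pN2 and pN3
are pooled as category 2. Kaplan–Meier estimation, the k-sample log-rank
test and Cox proportional-hazards fits use lifelines as the numerical
backend. Grade enters the Cox model as dummy indicators against the
lowest grade level; pT and pN enter ordinal-as-linear by default with a
categorical option for pT; models are complete-case, with dropped-row
counts attached to the fit. Non-convergence or separation is flagged on
the result rather than raised. `subset` provides the Stage I / pT1 /
cohort-selection filters used for subgroup analyses.

## Synthetic data

The generators define the simulation conditions under which the package
validates itself:

* **Mask pairs** — ground truth from nearest-seed (Voronoi) regions of
  random pattern blobs (default 64×64, 24 blobs, 15% background seeds);
  the prediction corrupts each pattern pixel through a known row-stochastic
  6×6 confusion matrix (default 90% diagonal with the remainder on
  severity-adjacent patterns). The generating matrix is returned so
  measured discrepancy rates have a binomial reference.
* **Rater panels** — default 283 items × 13 raters, mirroring the scale of
  a multi-institutional agreement study. Each item's latent pattern comes
  from a fixed prior (acinar-heavy, all six patterns represented); each
  rater reports it through an individual confusion matrix (diagonal
  accuracies spread 0.55–0.85). Expected pairwise kappa follows in closed
  form from the prior and the two confusion matrices, which is what the
  acceptance checks compare against.
* **Cohorts** — default 1000 cases in five prognostic groups with balanced
  allocation (0.2 each; equal arms identify every grade coefficient
  equally well in recovery experiments). Each case receives a composition
  whose dominant/secondary tier pair realises its group (dominant share
  0.50–0.70, secondary 0.15–0.30, bystanders kept strictly below the
  secondary), an exponential event time with hazard
  `baseline × exp(0.6 × (group − 1))` (baseline ln2/60 per month, i.e. a
  60-month median in the best group), and an independent exponential
  censoring time whose rate is solved numerically so the marginal
  censoring fraction hits the target (default 20%). pT, pN and age are
  drawn with mild positive correlation to the group but carry no direct
  hazard effect, so multivariate fits should reproduce the generating
  grade coefficients.

What the generators deliberately do **not** emulate: histological texture,
scanner or staining variation, spatial correlation between patterns in a
slide, informative censoring, and real covariate effect sizes. Passing
tests therefore demonstrate the correctness of the rule engines and
statistics, not clinical performance on real cohorts.

## Numerical and design choices

* Thresholds are strict (">"); boundary equality never upgrades.
* Percent tables whose per-case sum deviates from 100 by ≤ 1 point are
  renormalized with a warning; larger drift is an error.
* Ties (dominant pattern, modal vote) break toward higher severity and are
  flagged; nothing is dropped silently.
* All randomness flows through one `numpy` Generator seeded from the
  `SimSpec`; every generator is bit-reproducible given its seed.
* Problem sizes used by the validation suite: the exhaustive 5%-step
  composition simplex (53 130 compositions), 10 000-item panels for kappa
  calibration, 100 random 64×64 mask pairs, and 1000-case cohorts with 100
  replicates for median-ordering checks — sizes at which Monte-Carlo error
  is small relative to the stated tolerances.

## Known limitations

* The printed performance of the original segmentation network (e.g. its
  Dice on real annotated slides) is out of reach without the network and
  the slides; the segmentation metrics are validated against brute-force
  oracles instead.
* Weighted kappa over nominal patterns is order-dependent by construction;
  the severity order is a declared convention, not a fact of the data.
* The Cox harness offers a Schoenfeld-style convergence flag but no full
  proportional-hazards diagnostics.
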