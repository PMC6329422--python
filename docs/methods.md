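# Methods

## Measurement model

Responses are ordinal ratings in five categories, scored `k = 0..4` with
the orientation "more interference with quality of life = higher
category"; the two positively worded items (confidence in managing the
condition, ability to cope) are reversed before any analysis. "Does not
apply (I don't have symptoms right now)" — offered by two of the twelve
active items — is treated as *missing* during calibration and diagnostics
(the cell simply drops out of the likelihood) but contributes 0 points to
the raw total in operational scoring. Both conventions are kept
deliberately: the first mirrors how the item descriptives and the
calibration treat the code, the second mirrors the released scoring rule.

The core model is the grouped rating scale model (G-RSM):

    P(X_ni = k) ∝ exp( k (θ_n − δ_i) − Σ_{j≤k} τ_gj ),  τ_g0 ≡ 0,

with one threshold vector `τ_g` per rating-scale group (frequency-worded
vs intensity-worded items). Setting one group recovers the rating scale
model (RSM); giving every item its own group recovers the partial credit
model (PCM). All three are fit by the same code path.

### Estimation

Joint (unconditional) maximum likelihood — the estimation paradigm of the
Winsteps family — with these specifics:

- **Alternation with nested Newton loops.** Each outer cycle brings person
  measures to convergence given item parameters (1-D Newton per person,
  steps clipped at 1 logit), then items and thresholds to convergence
  given persons. Plain one-step alternation converges at a geometric rate
  of roughly 0.996 per cycle on this model class (thousands of cycles to
  1e-4), so the nested scheme is not cosmetic.
- **Threshold updates** use the full K×K Newton system per group (the
  Hessian blocks are cumulative-indicator covariances). Within the
  item/threshold inner loop the probabilities are refreshed between the
  difficulty step and the threshold step (Gauss–Seidel); updating both
  from the same probabilities oscillates. The flat direction "add c to all
  of a group's thresholds, subtract c from its items' difficulties" is
  projected out after every inner step; without this the inner loop cannot
  converge because the Newton steps wander along the invariant direction.
- **Identification.** Mean item difficulty 0; thresholds sum to 0 within
  each group. Both recenterings are applied as likelihood-preserving
  transformations (threshold recentering compensates the group's
  difficulties; difficulty recentering compensates the person measures).
- **Convergence.** Outer tolerance 1e-4 logits on the largest parameter
  change, cap 200 cycles; typical data converge in 15–20 cycles.
  Non-convergence flags the result rather than raising.
- **Extreme scores.** Persons/items whose observed raw score is at the
  floor or ceiling are excluded from calibration (they carry no
  information about their own location) and receive measures afterwards by
  inverting the test characteristic curve at the extreme raw score nudged
  0.3 score points inward. The same 0.3 nudge anchors the end rows of
  score tables.
- **Unobserved categories.** A category never observed within a group is
  collapsed onto its lower neighbour (logged); thresholds above the
  highest observed category are frozen at +30 logits, which removes the
  dead categories numerically without special-casing the likelihood.

Standard errors come from the corresponding observed-information diagonal
(persons, items) or the inverse threshold-information block (thresholds).

A property worth knowing: JMLE carries a small multiplicative scale
expansion (incidental-parameter bias). With 12 items and n=1000 it
inflates thresholds by roughly 10–15% of their magnitude; anchoring
persons at their generating values removes it entirely (this is how the
implementation was validated). Item difficulties, being small in
magnitude, are barely affected (RMSE ≈ 0.06 logits at n=1000), and the
scaled-score transform is immune because it standardizes within sample.

### Model comparison

The G-RSM vs RSM likelihood-ratio chi-square uses
df = (n_groups − 1) × (n_categories − 2): under sum-to-zero
identification each extra group frees categories−2 thresholds, giving
df = 3 for two groups and five categories. The statistic is computed from
JMLE log-likelihoods, which makes it approximate; a 500-replicate null
calibration at n=300 (common-threshold data, moderate ±2-logit
thresholds) puts the empirical rejection rate at ≈ 0.05–0.06 at α=.05, so
the approximation is serviceable at study-like sizes. PCM
item-characteristic-curve overlays per group, with a max-pairwise
sup-distance summary, support the grouping decision; the dissimilarity
summary is this package's construct (no canonical definition exists).

## Diagnostics

- **Fit statistics.** outfit_i = mean of squared standardized residuals;
  infit_i = Σ(x−E)² / ΣVar (information-weighted). Purging removes one
  item per round — the worst offender by outfit, ties broken by infit then
  instrument position — and recalibrates, stopping when everything fits at
  the 1.33 mean-square cutoff or 3 items remain.
- **Dimensionality.** Unrotated PCA of person-centered standardized
  residuals on the item correlation scale (eigenvalues sum to the number
  of items). Missing residuals are imputed as 0 ("no surprise"). Variance
  explained by the measures = (Σ(x−x̄)² − Σ(x−E)²) / Σ(x−x̄)².
- **DIF.** Anchored separate calibration: person measures and thresholds
  held at pooled estimates, each item's difficulty re-estimated per group;
  contrast tested with a two-sample t (joint SE, Welch-type df); flagged
  when |contrast| > 1.0 logit AND p < .05. Group labels are processed in
  sorted order so contrasts are reproducible and antisymmetric under label
  swaps. Age is dichotomized at the sample median by default
  (configurable); groups need ≥20 persons (configurable floor).
- **Targeting.** The Wright-map summary reports the mean offset between
  person and item distributions and the fraction of persons outside the
  item difficulty range; more than 10% below the easiest item flags
  low-end under-coverage (the instrument's known weak spot).

## Reliability and validity

Separation reliability R = (observed measure variance − mean squared SE) /
observed variance, clamped to [0,1]; the same formula serves persons and
items. Test-retest stability is a Pearson correlation over complete pairs.
Convergent-vs-discriminant comparison uses Steiger's z for dependent
correlations sharing the instrument's score (pooled-correlation covariance
form); the test is a module-level function and can be swapped.

## Scoring

Operational scoring uses the published conversion table verbatim: raw
totals 10–11 (attainable only via "does not apply") share the ≤12 row, and
the qualitative bands have deliberate gaps (90, 134, …) at scaled values
no raw total produces — `categorize` rejects them rather than guessing.
`build_score_table` reconstructs such a table from any calibration by
inverting the test characteristic curve at each raw total (extremes nudged
0.3 inward) and standardizing the calibration sample's person measures to
mean 100, SD 15 (sample SD, n−1), rounding half-up. How the released
table's own extreme rows were computed is undocumented; the embedded table
is authoritative for published scoring, and a recalibration on synthetic
data reproduces its interior shape (ogive spacing, widest steps at the
ends) but not its exact values, which depend on the original sample's
measure distribution.

## Synthetic data

The generator draws from the same category-probability function the engine
fits (single source of truth, cross-checked in tests against an
independently coded evaluation of the formula). Defaults emulate the
validation study:

| quantity | default | basis |
|---|---|---|
| persons | 126 (52.4% retested) | study sample |
| items | 12 active of a 14-item bank; 2 with "does not apply" | instrument |
| latent trait θ | N(0, 1) | person-map convention; implies person reliability ≈ 0.87–0.88 at n=126 |
| difficulties δ | −1.2 × centered item means | observed item descriptives |
| thresholds τ | frequency (−1.8,−0.6,0.6,1.8); intensity (−2.4,−0.8,0.8,2.4) | ordered, plausible spread |
| "does not apply" rate | 0.10 per eligible item | unreported; plausible |
| retest latent corr | 0.95 | high 5-day stability |
| demographics | 58.7% female, 85.7% white, age ≈ N(59, 13.5²) | study sample |

Mechanisms for diagnostics testing: off-model items respond uniformly at
random (a severe, reproducible misfit); DIF shifts one item's difficulty
by ±contrast/2 across a binary covariate; comparator variables are linear
factor loadings on standardized θ, with the ordinal stage variable's
latent loading inflated analytically so the *discretized* stage hits the
requested correlation. One root seed feeds named independent substreams
(trait, responses, misfit, DNA, retest, comparators, covariates), so
enabling one mechanism never perturbs the draws of another.

What the generator does **not** emulate: real response styles (central
tendency, acquiescence), local dependence between items, the treatment-mix
heterogeneity of the study sample, or its exact stage distribution.
Passing tests therefore demonstrate that the pipeline recovers truth under
its own model assumptions and detects planted violations — not that the
original sample's headline statistics are reproduced. Sample-dependent
published values (person reliability 0.87, retest r 0.89, first-contrast
eigenvalue 2.2, validity correlations) land in realistic neighbourhoods
under the preset but are not exact targets; notably the published retest
r = 0.89 slightly exceeds the attenuation ceiling implied by its own
person reliability, so no latent correlation reproduces it exactly.

## Problem sizes used in the test suite

Simulation-backed checks run at: parameter recovery n=1000; null LRT
calibration 500 replicates at n=300; DIF type-I 500 replicates at n=200
and power 200 replicates at n=600; item-fit power 200 replicates at n=400;
dimensionality null/alternative 60 replicates at n=500; threshold-order
recovery 50 replicates at n=1000; reliability recovery 100 replicates at
n=126. These sizes give stable pass/fail behavior at conventional
tolerances while keeping the full suite in the minutes range.

## Known limitations

- JMLE scale expansion (above): threshold estimates are inflated by
  ~10–15% at wide threshold spans; no bias correction is applied, matching
  the default behavior of the estimation paradigm emulated.
- The LRT is approximate under JMLE; its null calibration is verified
  empirically, not theoretically.
- The final 12-item composition of the published form is not identifiable
  from public sources; the default active set (bank items 1–12) is a
  documented configuration choice, not recovered content.
- Fits assume every person answered at least one non-extreme item; data
  consisting entirely of extreme responders cannot be calibrated.
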