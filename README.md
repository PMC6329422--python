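# ctclqol

Rasch-based development, validation and scoring toolkit for the
**MF/SS-CTCL QoL**, a 12-item patient-reported quality-of-life instrument
for people living with mycosis fungoides or Sézary syndrome cutaneous
T-cell lymphoma.

The package is aimed at psychometricians and outcomes researchers who want
to (a) score the published instrument exactly as released, and (b) re-run or
extend the full psychometric evaluation pipeline behind it — on their own
data or on synthetic data with the same structure, since the original
N=126 validation sample is not publicly deposited.

## What it implements

Each item is rated on five ordered categories (scored `k = 0..4` on the
analysis scale). The core measurement model is the **grouped rating scale
model** (G-RSM), a polytomous Rasch model in which the category thresholds
are shared within each of the two wording groups (frequency items:
"never…always"; intensity items: "not at all…very much"):

```
P(X_ni = k) ∝ exp( k·(θ_n − δ_i) − Σ_{j≤k} τ_gj ),   τ_g0 ≡ 0
```

with person measure `θ_n`, item difficulty `δ_i`, and Andrich thresholds
`τ_gj` of item *i*'s rating-scale group *g*. The plain rating scale model
(RSM, one shared threshold set) and the partial credit model (PCM,
item-specific thresholds) are the nested neighbours used for model
selection. Estimation is joint (unconditional) maximum likelihood with
alternating Newton steps, mean-zero item difficulties, sum-to-zero
thresholds per group, and the standard 0.3-score-point inward adjustment
for extreme raw scores.

On top of the engine:

- **Model comparison** — PCM item-characteristic-curve overlays per group,
  and a global likelihood-ratio chi-square of G-RSM vs RSM
  (df = (groups − 1) × (categories − 2) = 3 here).
- **Diagnostics** — infit/outfit mean-squares with iterative item purging
  at the conventional 1.33 cutoff; unrotated PCA of standardized residuals
  (first-contrast eigenvalue); threshold ordering and category response
  curves; test information / conditional SEM; person-to-item (Wright) map
  with a targeting summary; anchored DIF contrasts (flag: |contrast| > 1
  logit and p < .05) by gender, age, race.
- **Reliability & validity** — person/item separation reliability,
  test-retest Pearson stability, and convergent-vs-discriminant dependent
  correlations compared with Steiger's z.
- **Scoring** — the released raw→scaled conversion (mean 100, SD 15) and
  qualitative interpretation bands, embedded exactly as published, plus
  `build_score_table` to derive such a table from any new calibration.
- **Synthetic data** — a generator that draws responses from the same
  G-RSM, with optional off-model items, injected DIF, "does not apply"
  responding, retest administrations and comparator variables; a one-call
  `simulate_study()` mimics the validation study's layout (N=126, 12
  items, 52.4% retest, demographics).

## Worked example

```python
import ctclqol as cq

study = cq.simulate_study(seed=42)           # synthetic N=126 study
inst, rm = study["instrument"], study["responses"]

grsm = cq.fit(rm, inst, "grsm")
rsm = cq.fit(rm, inst, "rsm")
print(cq.lrt_grsm_vs_rsm(grsm, rsm))
# {'chi2': 25.88328232767526, 'df': 3, 'p': 1.0089416234008367e-05}

rep = cq.item_fit(grsm, rm)
print(rep.item.round(2).head(3))
#      infit  outfit
# q01   0.87    0.87
# q02   0.88    0.89
# q03   0.96    0.95

p = grsm.params
print(round(cq.separation_reliability(p.theta, p.theta_se), 3))  # 0.875

row = {f"q{i:02d}": 1 for i in range(1, 13)} | {"q05": 5, "q06": 5}
print(cq.published_score(row))
# {'raw': 12, 'scaled': 62, 'band': 'No to low interference'}
```

The likelihood-ratio test compares the grouped against the common-threshold
rating scale model (here it favours grouped thresholds); the fit table
shows infit/outfit mean-squares near 1 (model-consistent items); 0.875 is
the person separation reliability of the synthetic calibration; the final
call scores a minimum-interference response pattern on the published
conversion and band tables.

A command line mirrors the library:

```bash
ctclqol simulate --seed 42 --out-dir sim
ctclqol report --seed 42 --out-dir report        # 9-stage evaluation bundle
ctclqol score sim/responses.csv --lenient --out scores.csv
```

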