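# radstab

Segmentation-reliability analysis of radiomic features, and what it buys you
in survival prediction.

Radiomic features — histogram, shape, and gray-level texture statistics of a
tumour region — depend on the segmentation outline they are computed over,
and outlines vary between raters. `radstab` quantifies each feature's
inter-outline reliability with the one-way intraclass correlation
coefficient and tests the downstream consequence: proportional-hazards
survival models restricted to highly reliable features achieve higher and
less variable concordance than models given every feature.

The package is aimed at methodologists in quantitative imaging: it ships a
fully synthetic study bed — textured lesion phantoms, stochastically
perturbed segmentation outlines standing in for rater/network variability,
and survival times generated from a known proportional-hazards model — so
the whole pipeline is testable against ground truth on a laptop.

## The core quantities

**ICC(1).** For one feature, arrange values as an n lesions × k outlines
matrix. With between-lesion mean square MSB (df n−1) and within-lesion mean
square MSW (df n(k−1)),

    ICC(1) = (MSB − MSW) / (MSB + (k − 1) · MSW),

the fraction of total variance attributable to true between-lesion
differences. Features are grouped into quartiles and into three signatures:
*high* (ICC > 0.99), *low* (ICC < 0.75), *all*.

**Cox / Harrell's C.** Risk is the linear predictor of a Cox model
h(t|x) = h₀(t)·exp(xᵀβ), fit by Newton iterations on the Breslow partial
likelihood with sequential forward selection inside each training fold.
Harrell's C counts, over comparable pairs (tᵢ < tⱼ, eᵢ = 1), how often the
shorter-lived patient has the higher risk score (ties weight ½); 0.5 is
random, 1.0 perfect. Per signature, the model is fit once per fold on the
manual-outline features and evaluated on the test fold once per outline
variant, giving a C distribution whose mean and spread are compared across
signatures (Friedman, then pairwise Wilcoxon for location and Bartlett for
spread at a Bonferroni 0.05/2).

## Worked example

```python
import pandas as pd
from radstab import (CohortSpec, PerturbationSpec, make_cohort, crop_cohort,
                     CropRule, extract_all, FeatureConfig, icc_table,
                     threshold_signatures, stratified_folds, evaluate_signature)

cohort = make_cohort(CohortSpec(n_patients=40, k_manual=1, manual_amplitude_mm=0.0,
                                perturbation=PerturbationSpec(n_variants=60)),
                     master_seed=17)
kept, excluded = crop_cohort(cohort.cases, CropRule(box_size=40))
table = extract_all(kept, FeatureConfig())
l2p = {c.lesion_id: c.patient_id for c in cohort.cases}
table.index = pd.MultiIndex.from_tuples([(l2p[l], s) for l, s in table.index],
                                        names=["patient_id", "segmentation_id"])

icc = icc_table(table, "auto")
print(icc.head(5)[["feature_name", "icc"]].to_string(index=False))
sig = threshold_signatures(icc)
print(f"signatures: {len(sig.high)} high (ICC>0.99), "
      f"{len(sig.low)} low (ICC<0.75), {len(sig.all)} total")

cv = stratified_folds(cohort.survival, seed=17)
for name in ("high", "all", "low"):
    d = evaluate_signature(table, cohort.survival, sig.get(name), cv,
                           signature_name=name)
    print(f"{name:5s}  C mean {d.mean:.3f}   SD over variants {d.variant_sd:.4f}")
```

prints

```
                       feature_name      icc
        original.firstorder.Maximum 0.999959
   original.firstorder.Percentile90 0.997231
         original.firstorder.Energy 0.996253
original.firstorder.RootMeanSquared 0.978956
   original.shape2D.MaximumDiameter 0.957425
signatures: 3 high (ICC>0.99), 18 low (ICC<0.75), 56 total
high   C mean 0.788   SD over variants 0.0121
all    C mean 0.749   SD over variants 0.0244
low    C mean 0.725   SD over variants 0.0380
```

Reading it: coarse intensity summaries survive outline jitter almost
unchanged (ICC ≈ 1) and make up the high-reliability signature; the model
restricted to them predicts the (synthetically planted) survival signal best
and its concordance barely moves across the 60 outline variants, while the
low-reliability signature predicts worst with three times the spread.

The same analysis runs from the shell, driven by a YAML config:

```
radstab init-config --out config.yaml
radstab all --config config.yaml --out runs/demo --seed 17
radstab report --run-dir runs/demo
```

which writes per-stage CSV artifacts (feature table, ICC table with
quartiles and signature flags, per-signature C-index distributions, test
report) plus figure-ready data tables under `runs/demo/report/`.

## Layout

- `radstab.synthgen` — phantoms, outline perturbation, survival generation
- `radstab.preprocess` — box sizing, crop + exclusion rules, slice selection
- `radstab.features` — first-order, 2D shape, GLCM/GLRLM/GLSZM/GLDM,
  wavelet sub-bands
- `radstab.reliability` — ICC(1), quartiles, signatures, manual-vs-auto
- `radstab.survival` — `CoxPHModel` (scikit-learn style), Harrell's C,
  stratified CV, forward selection, signature evaluation, risk groups
- `radstab.stats` — Friedman / Wilcoxon / Bartlett / D'Agostino battery
- `radstab.pipeline`, `radstab.cli` — orchestration, caching, reports

Design rationale, parameter defaults and limitations: `docs/methods.md`.
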