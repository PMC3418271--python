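# lungct

Automated quantification of aerated lung volume in mice from
high-resolution micro-CT, for preclinical studies of pulmonary fibrosis
and emphysema. A decrease in aerated volume tracks restrictive (fibrotic)
disease; a dose-dependent increase tracks emphysematous airspace
enlargement — both without end-stage procedures, so individual animals
can be followed longitudinally.

The package implements the full analysis chain downstream of tomographic
reconstruction:

* **HU calibration** — two-point linear map from stored grayscale indices
  to Hounsfield units, anchored on a water/air phantom:
  `HU(g) = 1000·(g − g_water)/(g_water − g_air)`, so water → 0 HU and
  air → −1000 HU exactly.
* **Retrospective respiratory gating** — a pseudo-sinusoidal thorax-marker
  trace is segmented into breaths (trough → trough, i.e. initiation of
  inspiration to end-expiration); each projection is assigned to one of 4
  equal phase bins by `bin = ⌊4φ⌋` on its within-cycle phase fraction φ.
  Bin 0 yields the end-inspiratory volume (EIV), bin 3 the end-expiratory
  volume (EEV, the functional residual volume — the preferred endpoint,
  insensitive to anesthesia-induced gasping).
* **Fully automated lung segmentation** — threshold at air density
  (HU ≤ −580 euthanized, ≤ −383 in vivo), remove enclosed 2D air "pores"
  per slice to isolate external air, take the complement as a body ROI,
  erode its border by 10 px per slice, re-threshold inside the eroded
  ROI, and keep the largest 26-connected 3D component (the sweep). No
  seeds, no operator input.
* **Pressure-volume curves** — post-sacrifice volumes at decreasing
  airway pressures (30 → 3 cmH₂O) with trapezoidal area under the curve.
* **Study statistics** — within-subject SD from one-way ANOVA
  (`sw = √(residual MS)`), the 95% repeatability coefficient
  `1.96·√2·sw`, mean-vs-SD Spearman heteroscedasticity check, OLS
  agreement with 95% prediction bands, Welch t-tests, and noncentral-t/F
  power and sample-size calculations (G*Power-style).
* **Digital thorax phantom** — a seeded synthetic mouse thorax (4
  breathing phases, optional fibrotic consolidation and emphysematous
  dose scaling, sub-threshold speckle pockets) with exact noiseless
  ground truth, so the whole pipeline is testable with no scanner data.

## Worked example

```python
from lungct import (PhantomSpec, make_thorax_phantom, segment_aerated_lung,
                    respiratory_volumes, ttest_power, TTestPowerQuery,
                    ttest_sample_size)

spec = PhantomSpec(seed=1)                   # 200³ grid, 35 µm voxels, σ = 20 HU
volumes, truth = make_thorax_phantom(spec)   # 4 respiratory phases
results = [segment_aerated_lung(volumes[p]) for p in range(4)]
rv = respiratory_volumes(results)
print([round(v, 2) for v in rv.per_bin_mm3])
print(f"EIV = {rv.eiv_mm3:.2f} mm³, EEV = {rv.eev_mm3:.2f} mm³")
print(f"ground-truth EEV = {truth.lung_mm3[3]:.2f} mm³")

power = ttest_power(TTestPowerQuery(cohen_d=1.861, n1=5, n2=6))
n, total, achieved = ttest_sample_size(1.861, target_power=0.80)
print(f"post-hoc power: {100*power:.0f}%  |  80% design: {n} per group ({total} total)")
```

prints

```
[13.6, 12.67, 11.85, 11.19]
EIV = 13.60 mm³, EEV = 11.19 mm³
ground-truth EEV = 11.19 mm³
post-hoc power: 78%  |  80% design: 6 per group (12 total)
```

The four per-bin volumes deflate monotonically from end-inspiration to
end-expiration, and the segmented EEV recovers the phantom's noiseless
ground truth exactly at σ = 20 HU noise (the air/tissue contrast is ≈ 50σ).
The power numbers answer the study-design questions: an experiment with 5
vs 6 animals at effect size d = 1.861 had 78% power, and 6 per group
reach the conventional 80%.

The same operations are available from the shell:

```
lungct simulate --preset fibrosis --severity 0.3 --seed 7 --out phantom/
lungct quantify --input phantom/ --mode exvivo --out report.json
lungct power ttest --d 1.861 --n1 5 --n2 6
lungct stats repeatability --data repeats.csv
```

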