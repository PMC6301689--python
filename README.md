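# pvccs — partial-volume-corrected coronary calcium volume scoring

Coronary artery calcium (CAC) quantified in CT is a strong predictor of
cardiovascular events, but the clinical volume score — count every voxel of a
26-connected component at or above 130 HU and multiply by the voxel volume —
is notoriously sensitive to partial volume effects: at 3 mm slice thickness a
dense calcification smears across voxel boundaries and its apparent volume
can more than double, while a low-density lesion can shrink or vanish. This
package implements a per-lesion partial-volume-corrected volume score
(PVC-CS) alongside the clinical score (C-CS), plus a digital phantom
simulator and the agreement statistics needed to validate the method without
access to a physical scanner.

It is aimed at researchers in quantitative cardiac CT who want a
reproducible, desk-scale implementation of adaptive-threshold calcium
scoring, a controllable ground-truth phantom generator, or the evaluation
machinery (volume ratios, repeatability summaries, Bland–Altman, ICC).

## The method

For each lesion detected at 130 HU (26-connectivity):

1. **Region construction.** An extended segmentation collects voxels above
   90 HU that are 26-connected to the lesion, pruned to within *d₁* mm of the
   initial boundary, where *d₁* is the largest interior distance of the
   initial mask. A background shell collects non-calcification voxels within
   *d₂* mm of the calcification, *d₂* being the largest interior distance of
   the full calcification volume. Both distance transforms are Euclidean and
   corrected for voxel anisotropy.
2. **Adaptive threshold.** A two-component Gaussian mixture is fitted by EM
   to the pooled calcification + background intensities; the background
   component (μ_B, σ_B) defines

   Threshold = μ_B + FWHM_B / 2 = μ_B + √(2 ln 2) · σ_B.

3. **Partial volume content.** Every calcification voxel above the threshold
   partially contains calcium, with fraction

   PVC_i = (X_i − X_min) / (X_max − X_min),

   where X_min and X_max are the minimum and maximum intensity of the scored
   lesion voxels, and the corrected volume score is

   Volume_CAC = Σ_i PVC_i · Volume_voxel.

The simulator (`pvccs.phantom_sim`) emulates two physical phantom families —
nine cylindrical hydroxyapatite inserts (98.2 / 21.2 / 0.8 mm³ at 800 / 400 /
200 mg/cm³) in a thorax phantom with optional girth rings, and
circular-segment inserts (62.8 / 24.6 / 9.1 mm³) on artificial arteries in a
50 HU background with transverse motion at 0 / 10 / 30 mm/s — via analytic
rasterization on a supersampled grid, motion box blur, in-plane Gaussian PSF,
block-averaging to a 3 mm slice grid (the source of the partial volume
effect) and additive Gaussian noise, with exact analytic ground truth.

## Worked example

```python
import pvccs

spec = pvccs.make_ceora_spec("none", seed=0)          # 9-cylinder phantom
volume, truth = pvccs.simulate_acquisition(spec)       # 0.4x0.4x3 mm grid
result = pvccs.score_scan(volume)

from pvccs.evaluation import match_scores_to_inserts
table = match_scores_to_inserts(result, truth)
table = table[table.detected].assign(
    ccs_ratio=lambda d: d.ccs_mm3 / d.true_mm3,
    pvc_ratio=lambda d: d.pvc_mm3 / d.true_mm3,
)
print(table[["insert_id", "true_mm3", "ccs_mm3", "pvc_mm3",
             "ccs_ratio", "pvc_ratio"]].round(2).to_string(index=False))
print(f"totals: clinical {result.total_ccs_mm3:.1f} mm^3, "
      f"corrected {result.total_pvc_mm3:.1f} mm^3")
```

prints

```
 insert_id  true_mm3  ccs_mm3  pvc_mm3  ccs_ratio  pvc_ratio
 large_800     98.17   260.16    85.12       2.65       0.87
medium_800     21.21    48.48    20.02       2.29       0.94
 small_800      0.79     1.92     3.23       2.44       4.11
 large_400     98.17   201.12    75.49       2.05       0.77
medium_400     21.21    38.40    18.51       1.81       0.87
 large_200     98.17    87.84    55.94       0.89       0.57
medium_200     21.21    25.44    15.39       1.20       0.73
totals: clinical 663.4 mm^3, corrected 273.7 mm^3
```

The clinical score inflates the high- and medium-density inserts 1.8–2.7×
(partial volume spread keeps smeared voxels above 130 HU) while the corrected
score stays within ~25% of truth for the large and medium inserts; both
methods underestimate low-density lesions, the corrected score more so. The
two small 400/200 mg/cm³ inserts never reach 130 HU and go undetected.

A command line mirrors the library:

```bash
pvccs simulate --preset ceora --ring M --repeats 5 --seed 7 --out sim/
pvccs score --input sim/ceora_rep00.nii.gz --out scores/
pvccs evaluate --pairs pairs.csv --method pvc --out report/
```

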