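# collagenmap

Non-destructive collagen prescreening of archaeological bone from
near-infrared hyperspectral images.

## The problem

Radiocarbon dating of prehistoric bone requires extracting collagen, a
destructive step; a yield of at least 1 % by weight is the conventional
threshold for a datable sample. Many precious specimens cannot afford
blind sampling. Near-infrared hyperspectral imaging (NIR-HSI, 1000–2500 nm
push-broom line scan) records a full spectrum at every pixel, and collagen
has distinct NIR absorptions near 2040 nm (N–H combination), 2170 nm
(amide carbonyl overtone + N–H bend) and 2270 nm (C–H combination). A
multivariate calibration against wet-chemistry collagen yields turns the
cube into a quantitative, pixel-level collagen-percentage map — answering
both *how much* collagen a bone holds and *where* to cut, before touching
the sample.

`collagenmap` implements that pipeline for people running or evaluating
such prescreening: ENVI cube I/O with dark/white reflectance calibration,
the spectral preprocessing frozen into the calibration, PLS regression
with cross-validated model selection and permutation robustness tests,
false-colour mapping with automatic ROI selection and sampling-area
recommendation, and the collagen-yield arithmetic that produces the
reference values.

## The model

Each pixel (or per-sample representative profile) **x** on the wavelength
grid is preprocessed by

1. trimming bands below 1060 nm (poor detector signal-to-noise),
2. the standard normal variate transform,
   x ← (x − x̄)/s_x, cancelling per-spectrum scatter (gain and offset),
3. a second-order Savitzky–Golay derivative (15-point window, 3rd-degree
   polynomial), removing residual baseline shift and drift.

The calibration is PLS1 fitted by NIPALS on column mean-centred data:
for components a = 1…A,

    w_a ∝ X_aᵀ y,   t_a = X_a w_a,   p_a = X_aᵀ t_a / t_aᵀ t_a,
    q_a = yᵀ t_a / t_aᵀ t_a,         X_{a+1} = X_a − t_a p_aᵀ,

with regression vector **β** = W(PᵀW)⁻¹q and prediction
ŷ = ȳ + (x − x̄)ᵀβ. The number of latent variables A is chosen by
cross-validation over five cancellation groups as the smallest A
attaining the lowest RMSECV (root mean square error of cross-validation —
a dispersion parameter in % collagen). Robustness is probed by
re-randomising the CV groups (error should not move) and by permuting y
against X (error should collapse to ≈ SD(y)).

Because no real bone NIR-HSI dataset is publicly deposited, the package
ships a first-class synthetic generator (`collagenmap.synthetic`) whose
spectra carry collagen bands scaling linearly with collagen %, scatter,
heteroscedastic detector noise, background and soil-concretion pixels —
with ground truth returned for every draw. See `docs/methods.md` for the
generative model and its calibration.

## Worked example

```python
import numpy as np
from collagenmap import (
    SyntheticConfig, simulate_calibration, simulate_cube,
    PreprocessRecipe, fit_calibration, build_background_mask,
    build_concretion_mask, predict_map, recommend_sampling_area,
)
from collagenmap.synthetic import three_level_field

config = SyntheticConfig()
recipe = PreprocessRecipe()          # trim <1060 nm, SNV, SG(15, 3, d=2)

# calibrate: 59 synthetic bones (44 powders, 15 fragments), collagen U[0, 20]%
samples, _ = simulate_calibration(config=config, seed=1)
model, cv = fit_calibration(samples, config.wavelength_grid, recipe=recipe, seed=1)
print(f"chosen LV = {cv.chosen_lv}, RMSECV = {cv.rmsecv:.2f}%")

# predict a 100x100 cube with a three-level collagen field and 5% concretions
cube, truth = simulate_cube(100, 100, three_level_field(100, 100),
                            background_fraction=0.10, concretion_fraction=0.05,
                            config=config, seed=2)
fg = build_background_mask(cube, threshold=0.1)
clean = build_concretion_mask(cube, config.concretion_endmember(), 0.9,
                              recipe=recipe, within=fg)
pmap = predict_map(cube, clean, model)
print(f"map mean = {pmap.mean_pct:.2f} ± {cv.rmsecv:.1f}% "
      f"(spatial SD {pmap.sd_pct:.2f}%, {pmap.valid_mask.n_true} pixels)")

area = recommend_sampling_area(pmap, window_mm=5.0, min_collagen_pct=2.0)
print(f"cut here: {area.size_px}x{area.size_px} px window at "
      f"({area.row}, {area.col}), expected {area.mean_pct:.1f}% collagen")
```

prints

```
chosen LV = 2, RMSECV = 1.65%
map mean = 8.39 ± 1.7% (spatial SD 4.69%, 8500 pixels)
cut here: 10x10 px window at (4, 64), expected 13.1% collagen
```

The first line is the calibration: two latent variables suffice and
held-out predictions scatter by about 1.7 % collagen around the
reference yields. The map line reports the sample summary in the
`value ± RMSECV` convention (the spatial SD is the variability of the
collagen distribution, reported separately). The last line is the
recommendation of the most collagen-rich 5 mm square to cut; had every
window fallen below 2 %, the result would carry a flag advising against
destroying any material.

The same workflow is available from the shell:

```sh
collagenmap simulate  --out sim --seed 1
collagenmap calibrate --table sim/calibration.csv --out cal --seed 1
collagenmap predict   --model cal/model.json --cube sim/cube.hdr --out maps
collagenmap yield     --records extractions.csv --decimals 1
```

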