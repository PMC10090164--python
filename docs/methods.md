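# Methods

This note documents the models, numerical choices and limitations behind
`collagenmap`, in the spirit of a package reference manual. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Reflectance calibration

A push-broom scan yields raw counts per (scan line, cross-track pixel,
band). Reflectance is the flat-field ratio

    R = (raw − dark) / (white − dark)

with dark (closed-shutter) and white (Spectralon) references recorded per
cross-track pixel and band and broadcast along the scan axis; a
whole-frame `(bands,)` average is accepted as a fallback. Bands where
`white == dark` make the ratio undefined: they are dropped from the
returned cube with a warning rather than propagated as non-finite values.
Reflectance is clipped to `[0, 2]` — specular glints can exceed 1 — and
the unclipped values are retained in a QC side channel
(`SpectralCube.raw_unclipped`). Cubes are held as float64 regardless of
the on-disk integer type because the second-derivative step amplifies
quantisation noise. The ENVI header's wavelength list is authoritative
for the band axis.

## Preprocessing recipe

The frozen default is trim → SNV → Savitzky–Golay second derivative:

* **Trim**: bands with centres below 1060 nm are removed (detector
  efficiency makes that range noise-dominated). The boundary is closed on
  the retained side: centres ≥ 1060 nm are kept. On the default
  1000–2500 nm / 5.6 nm grid this leaves 257 of 268 bands.
* **SNV**: per-spectrum centring and scaling to unit sample SD (n−1
  denominator). Exactly cancels per-spectrum gain and offset; zero-variance
  spectra are fatal in calibration and silently dropped (with a logged
  count) in map mode, where a dead pixel should not abort a scan.
* **Savitzky–Golay derivative**: second derivative, 15-point window,
  third-degree polynomial, units scaled by the band spacing (per nm²).
  The half-window at each end, where the local fit hangs over the edge,
  is dropped rather than extrapolated — edge extrapolation fabricates
  high-leverage features. The feature count is therefore
  `bands_after_trim − (window − 1)` = 243 by default. The derivative
  requires a uniform grid (gaps within 5 % of the median spacing); a
  linear-interpolation resampler is provided for irregular axes.

Step order is configurable and recorded in the recipe; SNV-then-derivative
is the default because it makes scatter invariance exact *before*
differentiation. An optional log10(1/R) absorbance transform is off by
default (the pipeline operates on reflectance as read); it exists for
comparability with common chemometric practice. A fitted model embeds its
recipe verbatim, and prediction refuses wavelength grids that do not
match the grid the recipe was frozen on.

Representative per-sample profiles are the per-band **mean** over
unmasked pixels for powders and the per-band **median** for fragments:
fragments are physically more heterogeneous and the median resists
localized outliers (tested against constructed 10 %-outlier cubes).

## PLS1 and model selection

NIPALS PLS1 with X-only deflation; for a single response the inner loop
is non-iterative (`w ∝ Xᵀy` exactly), which makes independent
implementations bit-comparable. Scores are mutually orthogonal, the
predictor residual norm strictly decreases per component, and at full
rank the regression vector equals the ordinary least-squares solution on
centred data — all asserted in the test suite, with the normal equations
solved directly as the oracle and scikit-learn's `PLSRegression` as an
external cross-check (it is never the implementation).

Model complexity is chosen by cross-validation over five cancellation
groups (random assignment under a required seed; contiguous and
venetian-blind schemes are options, and the scheme is recorded in the
result). Mean-centring is recomputed on each training fold — centring on
the full set before CV leaks the held-out samples into the centres and
flatters RMSECV. The chosen LV is the smallest one whose RMSECV is within
1e-9 of the curve minimum (parsimony tie rule). The default LV ceiling is
`min(15, n − ceil(n/groups) − 1, p)`, keeping every training fold
solvable.

Two robustness procedures are distinguished explicitly:

* **randomisation**: the CV group assignment is re-drawn with the (X, y)
  pairing intact; for a stable model the RMSECV distribution stays at the
  model error;
* **permutation**: y is permuted against X and the full CV (including LV
  selection by the same first-minimum rule) repeated per permutation; the
  error collapses to roughly SD(y), the no-information level.

## Mapping, ROIs, sampling recommendation

Prediction runs every unmasked pixel through the frozen recipe and the
model. Negative predictions are retained in all statistics and clipped
only for display — the raw model output is the estimate, and per-sample
summaries are reported as `mean ± RMSECV` with the spatial SD (n−1)
reported separately as the variability of the collagen distribution.

ROIs: three half-open `[low, high)` collagen ranges — blue/green/red for
low/mid/high. Explicit ranges are honoured verbatim (overlap is an
error); auto mode splits the valid-value distribution at its 33.3rd and
66.7th percentiles. The top interval is closed above so the maximum pixel
belongs to red. The published maps' numeric colour cutoffs are not
public, so auto mode is a stated convention, not a reconstruction.

The sampling recommendation slides a square window (side in mm, converted
at the cube's pixel size) over fully-valid positions, maximising the
window-mean predicted collagen; ties break to the top-left-most window.
A best mean below the datability threshold (default 2 %) sets a warning
flag: at that level no material should be destroyed.

## Yield arithmetic

Fraction yield is `100 × extracted mass / starting mass`; the total is
the sum over the >30 kDa and <30 kDa ultrafiltration fractions. Stored
values are never rounded. Display rounding is half-up at the requested
precision, because published tables mix integer and two-decimal
renderings whose own rounding is internally inconsistent — raw values
are authoritative, rendering is presentation.

## Synthetic generator

The generator exists so every stage is testable with known ground truth.

* **Wavelength grid**: 1000–2500 nm at 5.6 nm (268 bands), the
  acquisition resolution.
* **Bone spectrum**: a smooth mineral baseline (gentle slope plus broad
  dips near 1450/1940/2330 nm for OH, water and carbonate) minus three
  Gaussian collagen bands at 2040/2170/2270 nm whose depths are linear in
  collagen % (0.0030/0.0035/0.0025 reflectance per %, widths 30/35/30 nm).
  Clean spectra stay within (0, 1.2); band depth at 20 % collagen is
  ~0.07, a subtle signal by design.
* **Scatter**: per-spectrum gain U(0.7, 1.3) and offset U(−0.05, 0.05),
  which the SNV step must cancel.
* **Detector noise**: additive Gaussian, SD 0.0025 reflectance,
  boosted 5× below 1060 nm — the physical reason that range is trimmed.
* **Matrix variability**: a per-sample perturbation of six broad random
  Gaussian bumps (centres and widths re-drawn every draw, so no fixed
  low-dimensional subspace a regression could learn away), amplitude SD
  0.04 for powders and 0.12 for fragments — grinding homogenises powders;
  this asymmetry is the rationale for median-vs-mean profile extraction.
* **Profiles vs pixels**: a calibration profile represents the mean or
  median over a whole masked sample, so it carries detector noise reduced
  by `1/sqrt(profile_pixel_count)` (default 400) while the sample-level
  matrix perturbation survives averaging. Cube pixels carry full
  per-pixel scatter and noise; spatial heterogeneity belongs in the
  collagen field itself.
* **Noise calibration**: the perturbation SDs were calibrated once so
  that a known-direction projection oracle (regress collagen on the
  projection of the preprocessed spectrum onto the generator's per-%
  feature direction) recovers collagen with RMSE near 2 % on the
  59-sample study design — the working error level of the method — and
  then frozen. The pipeline's own RMSECV on those conditions is measured
  by the tests and the acceptance script, not assumed.
* **Cubes**: background pixels form a deterministic border frame of
  near-zero reflectance; concretion pixels are scattered over the object
  and drawn from a distinct soil-crust endmember (clay-like bands at
  1415/1915/2207 nm). Ground-truth masks partition the frame exactly.

What the generator does **not** emulate: radiative transfer or NIR
penetration depth, wavelength-dependent instrument response drift,
spatially correlated noise, real diagenetic chemistry, or any specific
archaeological specimen. Passing the synthetic recovery tests shows the
pipeline is correct and well-conditioned at the method's working noise
level; it does not certify accuracy on real bones, which requires a real
calibration set.

## Problem sizes

The test suite and acceptance script use the study-sized designs
throughout: 59-sample calibrations (44 powders, 15 fragments, collagen
uniform on [0, 20] %), 50 permutations/randomisations, and a 100×100
cube (10 % background, 5 % concretions) for end-to-end recovery; smaller
grids are used where only shape or algebra is being exercised.

## Known limitations

* PLS1 only; a single response per model (the method has one response).
  No PLS-DA classification, no variable selection, no per-pixel
  uncertainty beyond the map SD.
* Concretion masking is correlation-based against a supplied reference
  spectrum; it does not discover unknown contaminant endmembers.
* The ENVI reader covers the plain header + flat-binary layout (BIL,
  BIP, BSQ, standard dtype codes); exotic vendor extensions are out of
  scope.
* Pixel size is carried as metadata only; no spatial registration or
  sub-pixel modelling.
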