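"""Pixel-level collagen maps, false-colour rendering, and ROI selection.

The fitted PLS model is applied to every unmasked pixel spectrum (through
the model's frozen preprocessing recipe), yielding a collagen-% map whose
mean and SD summarise the sample. Maps are rendered blue (low collagen)
to red (high); three ROIs — low/mid/high predicted collagen — are either
given explicitly as numeric ranges or derived automatically from the
map's value tertiles, and each ROI's mean NIR spectrum can be extracted.
A sliding-window search recommends the most collagen-rich square area to
cut for extraction, with a warning when even the best window falls below
the datability threshold.

Negative predictions are retained in all statistics and clipped only for
display: raw model output is the authoritative estimate.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemometrics import PLSModel
from .io import SpectralCube
from .preprocess import PixelMask, apply_recipe_matrix, apply_recipe

__all__ = [
    "PredictionMap",
    "ROISet",
    "SamplingArea",
    "predict_map",
    "render_map",
    "select_rois",
    "roi_mean_spectrum",
    "recommend_sampling_area",
]

logger = logging.getLogger(__name__)

ROI_LABELS = ("blue", "green", "red")


@dataclass
class PredictionMap:
    """Per-pixel predicted collagen % with a validity mask and summary stats."""

    values: np.ndarray            # 2-D, NaN on invalid pixels
    valid_mask: PixelMask
    mean_pct: float
    sd_pct: float
    scale: str = "per_sample"
    pixel_size_mm: float = 0.5

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask.grid]


@dataclass
class ROISet:
    """Three disjoint collagen-% ranges with their pixel masks and spectra."""

    ranges: tuple[tuple[float, float], ...]
    masks: tuple[PixelMask, ...]
    labels: tuple[str, ...] = ROI_LABELS
    mean_spectra: dict = field(default_factory=dict)


@dataclass
class SamplingArea:
    """Recommended square to cut for extraction: position, size, expected %."""

    row: int
    col: int
    size_px: int
    mean_pct: float
    below_threshold: bool


def predict_map(
    cube: SpectralCube,
    mask: PixelMask,
    model: PLSModel,
) -> PredictionMap:
    """Predict collagen % for every unmasked pixel through the model's recipe.

    Pixels whose spectra are degenerate under the recipe (zero variance at
    the SNV step) are dropped from the valid mask with a logged count. The
    summary mean and SD (n−1 denominator) run over valid pixels only.
    """
    if cube.kind != "reflectance":
        raise ValueError(f"expected a reflectance cube, got kind={cube.kind!r}")
    if mask.grid.shape != cube.data.shape[:2]:
        raise ValueError("mask dims do not match cube")
    if cube.wavelengths.size != model.wavelengths.size or not np.allclose(
        cube.wavelengths, model.wavelengths
    ):
        raise ValueError(
            "cube wavelength grid does not match the grid the model's recipe "
            "was frozen on"
        )
    idx = np.argwhere(mask.grid)
    if idx.size == 0:
        raise ValueError("mask selects no pixel")
    X = cube.data[mask.grid]
    feats, valid, _ = apply_recipe_matrix(X, model.recipe, cube.wavelengths)
    n_dropped = int(np.sum(~valid))
    if n_dropped:
        logger.warning(
            "%d pixel(s) dropped from map: degenerate under the recipe",
            n_dropped,
        )
    if not np.any(valid):
        raise ValueError("no valid pixel after preprocessing")

    preds = model.predict_matrix(feats[valid])
    values = np.full(cube.data.shape[:2], np.nan)
    ok_idx = idx[valid]
    values[ok_idx[:, 0], ok_idx[:, 1]] = preds

    grid = np.zeros(cube.data.shape[:2], dtype=bool)
    grid[ok_idx[:, 0], ok_idx[:, 1]] = True
    sd = float(np.std(preds, ddof=1)) if preds.size > 1 else 0.0
    return PredictionMap(
        values=values,
        valid_mask=PixelMask(grid, provenance=mask.provenance),
        mean_pct=float(np.mean(preds)),
        sd_pct=sd,
        pixel_size_mm=cube.pixel_size_mm,
    )


def render_map(
    pmap: PredictionMap,
    out_path: str | Path,
    scale: str = "per_sample",
    vmin: float | None = None,
    vmax: float | None = None,
    clip_negative: bool = False,
) -> None:
    """Render a blue-to-red false-colour PNG with a collagen-% colour bar.

    ``per_sample`` scales the colour ramp to the map's own [min, max];
    ``global`` uses the caller's fixed ``vmin``/``vmax``. Invalid pixels
    render neutral grey. ``clip_negative`` clips displayed values at 0
    without touching the stored statistics.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    vals = pmap.values.copy()
    if clip_negative:
        vals = np.where(np.isnan(vals), np.nan, np.clip(vals, 0.0, None))
    masked = np.ma.masked_invalid(vals)
    if scale == "per_sample":
        lo, hi = float(masked.min()), float(masked.max())
    elif scale == "global":
        if vmin is None or vmax is None:
            raise ValueError("global scale requires vmin and vmax")
        lo, hi = vmin, vmax
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if lo == hi:
        hi = lo + 1e-9

    cmap = plt.get_cmap("jet").copy()
    cmap.set_bad(color="0.6")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(masked, cmap=cmap, vmin=lo, vmax=hi, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="collagen (%)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(Path(out_path), dpi=120, bbox_inches="tight")
    plt.close(fig)


def select_rois(
    pmap: PredictionMap,
    ranges: tuple[tuple[float, float], ...] | None = None,
) -> ROISet:
    """Partition valid pixels into low/mid/high (blue/green/red) ROIs.

    Explicit ``ranges`` — three half-open ``[low, high)`` intervals — are
    honoured verbatim and must not overlap. Auto mode splits the valid
    value distribution at its 33.3rd and 66.7th percentiles; the top
    interval is closed above so the maximum pixel belongs to red.
    """
    vals = pmap.valid_values()
    if vals.size == 0:
        raise ValueError("map has no valid pixel")
    if ranges is None:
        p1, p2 = np.percentile(vals, [33.3, 66.7])
        ranges = (
            (-np.inf, float(p1)),
            (float(p1), float(p2)),
            (float(p2), np.inf),
        )
        auto = True
    else:
        if len(ranges) != 3:
            raise ValueError("exactly three ROI ranges required")
        sorted_r = sorted(ranges)
        for (lo1, hi1), (lo2, hi2) in zip(sorted_r, sorted_r[1:]):
            if hi1 > lo2:
                raise ValueError(
                    f"ROI ranges overlap: [{lo1}, {hi1}) and [{lo2}, {hi2})"
                )
        auto = False

    masks = []
    vmax = np.nanmax(pmap.values[pmap.valid_mask.grid])
    for i, (lo, hi) in enumerate(ranges):
        grid = pmap.valid_mask.grid & (pmap.values >= lo) & (pmap.values < hi)
        # closed top edge of the last interval: the maximum belongs to red
        if i == len(ranges) - 1 and np.isfinite(hi):
            grid |= pmap.valid_mask.grid & (pmap.values == hi)
        masks.append(PixelMask(grid, provenance="manual"))
    for label, m in zip(ROI_LABELS, masks):
        if m.n_true == 0:
            warnings.warn(f"ROI {label!r} captured no pixel", stacklevel=2)
    if auto:
        # degenerate distributions collapse the percentiles; everything in blue
        pass
    return ROISet(ranges=tuple(ranges), masks=tuple(masks))


def roi_mean_spectrum(
    cube: SpectralCube,
    roi_mask: PixelMask,
    recipe=None,
    preprocessed: bool = False,
) -> np.ndarray:
    """Mean spectrum over ROI pixels, raw or recipe-preprocessed."""
    if roi_mask.n_true == 0:
        raise ValueError("empty ROI")
    pixels = cube.data[roi_mask.grid]
    if preprocessed:
        if recipe is None:
            raise ValueError("preprocessed=True requires a recipe")
        feats, valid, _ = apply_recipe_matrix(pixels, recipe, cube.wavelengths)
        if not np.any(valid):
            raise ValueError("no valid ROI pixel after preprocessing")
        return feats[valid].mean(axis=0)
    return pixels.mean(axis=0)


def recommend_sampling_area(
    pmap: PredictionMap,
    window_mm: float,
    min_collagen_pct: float = 2.0,
) -> SamplingArea:
    """Best square window to cut: maximises window-mean predicted collagen.

    Only windows whose pixels are all valid compete. Ties break to the
    top-left-most window (row-major). When even the best window's mean
    falls below ``min_collagen_pct``, the result is flagged — destroying
    material for so little collagen is not worthwhile.
    """
    size = max(1, int(round(window_mm / pmap.pixel_size_mm)))
    rows, cols = pmap.values.shape
    if size > rows or size > cols:
        raise ValueError(
            f"window of {size} px exceeds the {rows}x{cols} map extent"
        )
    vals = np.where(pmap.valid_mask.grid, pmap.values, 0.0)
    valid = pmap.valid_mask.grid.astype(float)

    # sliding-window sums via 2-D cumulative sums
    def window_sums(a: np.ndarray) -> np.ndarray:
        c = np.cumsum(np.cumsum(a, axis=0), axis=1)
        c = np.pad(c, ((1, 0), (1, 0)))
        return (
            c[size:, size:] - c[:-size, size:] - c[size:, :-size]
            + c[:-size, :-size]
        )

    sums = window_sums(vals)
    counts = window_sums(valid)
    full = counts >= size * size - 0.5
    if not np.any(full):
        raise ValueError("no window lies fully inside the valid mask")
    means = np.where(full, sums / (size * size), -np.inf)
    flat_best = int(np.argmax(means))  # argmax takes the first (row-major) max
    r, c = np.unravel_index(flat_best, means.shape)
    best_mean = float(means[r, c])
    return SamplingArea(
        row=int(r),
        col=int(c),
        size_px=size,
        mean_pct=best_mean,
        below_threshold=best_mean < min_collagen_pct,
    )


def export_map(
    pmap: PredictionMap,
    out_dir: str | Path,
    stem: str,
    model_meta: dict | None = None,
    render: bool = True,
    scale: str = "per_sample",
    clip_negative: bool = False,
) -> dict:
    """Write TIFF (float32 values), optional PNG render, and a JSON sidecar."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        out_dir / f"{stem}.tif", pmap.values.astype(np.float32)
    )
    sidecar = {
        "mean_pct": pmap.mean_pct,
        "sd_pct": pmap.sd_pct,
        "n_valid": pmap.valid_mask.n_true,
        "scale": scale,
        "pixel_size_mm": pmap.pixel_size_mm,
    }
    if model_meta:
        sidecar["model"] = model_meta
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    if render:
        render_map(
            pmap, out_dir / f"{stem}.png", scale=scale,
            clip_negative=clip_negative,
        )
    return sidecar
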