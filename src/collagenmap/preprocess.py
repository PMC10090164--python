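"""Spectral pre-treatments and pixel masking.

The calibration recipe frozen into every fitted model is the composition
trim -> (optional absorbance) -> SNV -> Savitzky-Golay second derivative:

* wavelengths below 1060 nm are removed (detector noise dominates there);
* the standard normal variate transform (SNV) centres each spectrum and
  scales it to unit sample variance, cancelling per-spectrum multiplicative
  and additive scatter;
* a second-order Savitzky-Golay derivative (15-point window, third-degree
  polynomial) removes residual baseline shift and drift, leaving band
  intensity and shape as the only carriers of chemical information.

Representative per-sample profiles are the per-band mean over unmasked
pixels for powders and the per-band median for fragments (fragments are
more heterogeneous; the median is the more robust descriptor).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .io import SpectralCube

__all__ = [
    "PixelMask",
    "PreprocessRecipe",
    "DegenerateSpectrumError",
    "NonUniformGridError",
    "snv",
    "savgol_derivative",
    "trim_wavelengths",
    "extract_profile",
    "apply_recipe",
    "apply_recipe_matrix",
    "build_background_mask",
    "build_concretion_mask",
    "resample_to_uniform",
]


class DegenerateSpectrumError(ValueError):
    """Zero-variance spectrum: SNV (and correlation) are undefined."""


class NonUniformGridError(ValueError):
    """Wavelength spacing too irregular for a Savitzky-Golay derivative."""


MASK_PROVENANCES = ("manual", "background_auto", "concretion")


@dataclass
class PixelMask:
    """Boolean participation mask over a cube's spatial grid (True = keep)."""

    grid: np.ndarray
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.provenance not in MASK_PROVENANCES:
            raise ValueError(
                f"provenance must be one of {MASK_PROVENANCES}, got {self.provenance!r}"
            )

    @property
    def n_true(self) -> int:
        return int(self.grid.sum())

    def intersect(self, other: "PixelMask") -> "PixelMask":
        if self.grid.shape != other.grid.shape:
            raise ValueError("mask shapes differ")
        return PixelMask(self.grid & other.grid, provenance=self.provenance)

    # -- I/O ---------------------------------------------------------------
    def to_png(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray((self.grid.astype(np.uint8) * 255)).save(Path(path))

    @classmethod
    def from_png(cls, path: str | Path, provenance: str = "manual") -> "PixelMask":
        from PIL import Image

        arr = np.asarray(Image.open(Path(path)).convert("L"))
        return cls(arr >= 128, provenance=provenance)

    def to_rle_json(self, path: str | Path) -> None:
        """Row-major run-length encoding, first run counts False pixels."""
        flat = self.grid.ravel()
        runs: list[int] = []
        current, count = False, 0
        for v in flat:
            if v == current:
                count += 1
            else:
                runs.append(count)
                current, count = v, 1
        runs.append(count)
        payload = {
            "shape": list(self.grid.shape),
            "provenance": self.provenance,
            "runs": runs,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_rle_json(cls, path: str | Path) -> "PixelMask":
        payload = json.loads(Path(path).read_text())
        flat = np.zeros(int(np.prod(payload["shape"])), dtype=bool)
        pos, value = 0, False
        for run in payload["runs"]:
            flat[pos : pos + run] = value
            pos += run
            value = not value
        return cls(flat.reshape(payload["shape"]), provenance=payload["provenance"])


@dataclass
class PreprocessRecipe:
    """Frozen preprocessing recipe shared by a model and everything it scores.

    Steps listed in ``step_order`` are applied in sequence; a step is also
    gated by its own switch (``snv``/``absorbance_transform`` flags, trim
    bounds set to ``None`` disable trimming). The Savitzky-Golay derivative
    marks half a window at each end invalid and drops it, so the output
    feature count is ``bands_after_trim - (sg_window - 1)``.
    """

    trim_low_nm: float | None = 1060.0
    trim_high_nm: float | None = None
    snv: bool = True
    sg_window: int = 15
    sg_polyorder: int = 3
    sg_derivative_order: int = 2
    absorbance_transform: bool = False
    step_order: tuple[str, ...] = ("trim", "absorbance", "snv", "derivative")

    def __post_init__(self) -> None:
        self.step_order = tuple(self.step_order)
        known = {"trim", "absorbance", "snv", "derivative"}
        unknown = set(self.step_order) - known
        if unknown:
            raise ValueError(f"unknown recipe steps: {sorted(unknown)}")
        if "derivative" in self.step_order:
            if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
                raise ValueError(
                    "sg_window must be odd and greater than sg_polyorder"
                )
            if self.sg_polyorder < self.sg_derivative_order:
                raise ValueError("sg_polyorder must be >= sg_derivative_order")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["step_order"] = list(self.step_order)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessRecipe":
        d = dict(d)
        d["step_order"] = tuple(d.get("step_order", ()))
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "PreprocessRecipe":
        return cls.from_dict(json.loads(s))

    # -- geometry ----------------------------------------------------------
    def output_wavelengths(self, wavelengths: np.ndarray) -> np.ndarray:
        """Wavelength axis of the preprocessed feature vector."""
        wl = np.asarray(wavelengths, dtype=float)
        for step in self.step_order:
            if step == "trim" and (
                self.trim_low_nm is not None or self.trim_high_nm is not None
            ):
                lo = -np.inf if self.trim_low_nm is None else self.trim_low_nm
                hi = np.inf if self.trim_high_nm is None else self.trim_high_nm
                wl = wl[(wl >= lo) & (wl <= hi)]
            elif step == "derivative":
                half = self.sg_window // 2
                wl = wl[half : wl.size - half]
        return wl

    def n_output_features(self, wavelengths: np.ndarray) -> int:
        return self.output_wavelengths(wavelengths).size


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------

def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale to unit sample SD (ddof=1)."""
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("snv expects a 1-D spectrum of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSpectrumError("zero-variance spectrum: SNV undefined")
    return (x - x.mean()) / sd


def _snv_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise SNV; returns (transformed, valid_rows). Invalid rows zeroed."""
    sd = X.std(axis=1, ddof=1)
    valid = sd > 0
    out = np.zeros_like(X)
    if np.any(valid):
        out[valid] = (X[valid] - X[valid].mean(axis=1, keepdims=True)) / sd[
            valid, None
        ]
    return out, valid


def uniform_spacing(wavelengths: np.ndarray, rel_tol: float = 0.05) -> float:
    """Median band spacing in nm; raises if any gap deviates more than rel_tol."""
    wl = np.asarray(wavelengths, dtype=float)
    gaps = np.diff(wl)
    spacing = float(np.median(gaps))
    if spacing <= 0:
        raise NonUniformGridError("wavelengths not increasing")
    if np.max(np.abs(gaps - spacing)) > rel_tol * spacing:
        raise NonUniformGridError(
            "wavelength grid is non-uniform beyond tolerance; resample first "
            "(see resample_to_uniform)"
        )
    return spacing


def resample_to_uniform(
    spectrum: np.ndarray, wavelengths: np.ndarray, n: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolation resampling onto a uniform grid spanning the input."""
    wl = np.asarray(wavelengths, dtype=float)
    x = np.asarray(spectrum, dtype=float)
    if n is None:
        n = wl.size
    grid = np.linspace(wl[0], wl[-1], n)
    return np.interp(grid, wl, x), grid


def savgol_derivative(
    spectrum: np.ndarray,
    window: int = 15,
    polyorder: int = 3,
    deriv: int = 2,
    spacing_nm: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay derivative with the edge half-windows dropped.

    Exact (to rounding) for polynomials of degree <= ``polyorder``; output
    units are input units per nm**deriv. The ``window - 1`` edge points,
    where the local fit hangs over the end of the spectrum, are removed
    rather than extrapolated.
    """
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if polyorder < deriv:
        raise ValueError("polyorder must be >= deriv")
    if x.shape[-1] < window:
        raise ValueError(
            f"window {window} exceeds spectrum length {x.shape[-1]}"
        )
    full = savgol_filter(
        x, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=spacing_nm, axis=-1,
    )
    half = window // 2
    return full[..., half : x.shape[-1] - half]


def trim_wavelengths(
    obj: SpectralCube | np.ndarray,
    low_nm: float | None = None,
    high_nm: float | None = None,
    wavelengths: np.ndarray | None = None,
):
    """Drop bands with centres outside ``[low_nm, high_nm]`` (closed bounds).

    For a :class:`~collagenmap.io.SpectralCube` the trimmed cube is
    returned; for a bare spectrum (``wavelengths`` required) the pair
    ``(trimmed_values, trimmed_wavelengths)`` is returned.
    """
    lo = -np.inf if low_nm is None else float(low_nm)
    hi = np.inf if high_nm is None else float(high_nm)
    if isinstance(obj, SpectralCube):
        keep = (obj.wavelengths >= lo) & (obj.wavelengths <= hi)
        if not np.any(keep):
            raise ValueError("trim removed every band")
        return SpectralCube(
            data=obj.data[:, :, keep],
            wavelengths=obj.wavelengths[keep],
            pixel_size_mm=obj.pixel_size_mm,
            kind=obj.kind,
        )
    if wavelengths is None:
        raise ValueError("wavelengths required when trimming a bare spectrum")
    wl = np.asarray(wavelengths, dtype=float)
    x = np.asarray(obj, dtype=float)
    keep = (wl >= lo) & (wl <= hi)
    if not np.any(keep):
        raise ValueError("trim removed every band")
    return x[..., keep], wl[keep]


def extract_profile(
    cube: SpectralCube, mask: PixelMask, form: str
) -> np.ndarray:
    """Representative spectrum: per-band mean (powder) or median (fragment)."""
    if form not in ("powder", "fragment"):
        raise ValueError(f"form must be 'powder' or 'fragment', got {form!r}")
    if mask.grid.shape != cube.data.shape[:2]:
        raise ValueError("mask dims do not match cube")
    if mask.n_true == 0:
        raise ValueError("mask selects no pixel; cannot extract a profile")
    pixels = cube.data[mask.grid]
    if form == "powder":
        return pixels.mean(axis=0)
    return np.median(pixels, axis=0)


# ---------------------------------------------------------------------------
# Recipe application
# ---------------------------------------------------------------------------

def apply_recipe_matrix(
    X: np.ndarray,
    recipe: PreprocessRecipe,
    wavelengths: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply a recipe to rows of spectra.

    Returns ``(features, valid_rows, out_wavelengths)``. Rows that become
    degenerate at the SNV step (zero variance) are flagged False in
    ``valid_rows`` and zeroed; callers in calibration mode treat them as
    fatal, map mode drops them with a count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    wl = np.asarray(wavelengths, dtype=float)
    if X.shape[1] != wl.size:
        raise ValueError(
            f"spectra have {X.shape[1]} bands but wavelength axis has {wl.size}"
        )
    valid = np.ones(X.shape[0], dtype=bool)
    for step in recipe.step_order:
        if step == "trim":
            if recipe.trim_low_nm is None and recipe.trim_high_nm is None:
                continue
            X, wl = trim_wavelengths(
                X, recipe.trim_low_nm, recipe.trim_high_nm, wavelengths=wl
            )
        elif step == "absorbance":
            if not recipe.absorbance_transform:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                X = np.log10(1.0 / np.clip(X, 1e-8, None))
        elif step == "snv":
            if not recipe.snv:
                continue
            X, ok = _snv_matrix(X)
            valid &= ok
        elif step == "derivative":
            spacing = uniform_spacing(wl)
            if wl.size < recipe.sg_window:
                raise ValueError(
                    f"only {wl.size} bands remain but the SG window needs "
                    f"{recipe.sg_window}"
                )
            X = savgol_derivative(
                X,
                window=recipe.sg_window,
                polyorder=recipe.sg_polyorder,
                deriv=recipe.sg_derivative_order,
                spacing_nm=spacing,
            )
            half = recipe.sg_window // 2
            wl = wl[half : wl.size - half]
    return X, valid, wl


def apply_recipe(
    spectrum: np.ndarray,
    recipe: PreprocessRecipe,
    wavelengths: np.ndarray,
) -> np.ndarray:
    """Apply a recipe to one spectrum; degenerate spectra raise."""
    X, valid, _ = apply_recipe_matrix(spectrum[None, :], recipe, wavelengths)
    if not valid[0]:
        raise DegenerateSpectrumError(
            "spectrum has zero variance; SNV is undefined"
        )
    return X[0]


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def build_background_mask(
    cube: SpectralCube,
    polygons: Sequence[Sequence[Sequence[float]]] | None = None,
    threshold: float | None = None,
) -> PixelMask:
    """Foreground mask by manual polygons or an auto reflectance threshold.

    Manual mode rasterises ``[row, col]`` vertex polygons (their union is
    the foreground). Auto mode keeps pixels whose mean reflectance exceeds
    ``threshold`` — dark background falls below it.
    """
    if (polygons is None) == (threshold is None):
        raise ValueError("provide exactly one of polygons or threshold")
    rows, cols = cube.rows, cube.cols
    if polygons is not None:
        from matplotlib.path import Path as MplPath

        grid = np.zeros((rows, cols), dtype=bool)
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        points = np.column_stack([rr.ravel(), cc.ravel()])
        for poly in polygons:
            verts = np.asarray(poly, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ValueError("each polygon needs >= 3 [row, col] vertices")
            path = MplPath(verts)
            inside = path.contains_points(points, radius=0.5)
            grid |= inside.reshape(rows, cols)
        provenance = "manual"
    else:
        mean_r = cube.data.mean(axis=2)
        grid = mean_r > threshold
        provenance = "background_auto"
    if not grid.any():
        raise ValueError(
            "background mask is empty; revise the polygons or threshold"
        )
    return PixelMask(grid, provenance=provenance)


def build_concretion_mask(
    cube: SpectralCube,
    reference_spectrum: np.ndarray,
    correlation_floor: float = 0.9,
    recipe: PreprocessRecipe | None = None,
    within: PixelMask | None = None,
) -> PixelMask:
    """Mask of CLEAN pixels (True) by correlation against a concretion spectrum.

    Each candidate pixel's recipe-preprocessed spectrum is Pearson-correlated
    with the preprocessed concretion reference; pixels at or above
    ``correlation_floor`` are excluded. Zero-variance pixels (correlation
    undefined) are excluded too and counted in a warning.
    """
    if recipe is None:
        recipe = PreprocessRecipe()
    ref = np.asarray(reference_spectrum, dtype=float)
    if ref.size != cube.n_bands:
        raise ValueError("reference spectrum not on the cube's wavelength grid")
    base = (
        np.ones((cube.rows, cube.cols), dtype=bool)
        if within is None
        else within.grid
    )
    idx = np.argwhere(base)
    X = cube.data[base]
    feats, valid, _ = apply_recipe_matrix(X, recipe, cube.wavelengths)
    ref_feat = apply_recipe(ref, recipe, cube.wavelengths)

    rc = ref_feat - ref_feat.mean()
    rnorm = np.linalg.norm(rc)
    fc = feats - feats.mean(axis=1, keepdims=True)
    fnorm = np.linalg.norm(fc, axis=1)
    corr_ok = valid & (fnorm > 0) & (rnorm > 0)
    corr = np.zeros(feats.shape[0])
    corr[corr_ok] = fc[corr_ok] @ rc / (fnorm[corr_ok] * rnorm)

    clean = corr_ok & (corr < correlation_floor)
    n_degenerate = int(np.sum(~corr_ok))
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} pixel(s) had undefined correlation (zero "
            "variance) and were excluded",
            stacklevel=2,
        )
    grid = np.zeros((cube.rows, cube.cols), dtype=bool)
    grid[idx[clean, 0], idx[clean, 1]] = True
    return PixelMask(grid, provenance="concretion")
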