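"""ENVI hyperspectral cube I/O and reflectance calibration.

A push-broom NIR-HSI scan yields a three-dimensional array in which the
first two axes are spatial (scan line, cross-track pixel) and the third is
spectral. This module reads and writes such cubes in the ENVI convention
(an ASCII ``.hdr`` header next to a flat binary payload, in any of the
three standard interleaves) and converts raw sensor counts to reflectance
against dark (closed-shutter) and white (Spectralon) reference frames.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralCube",
    "ReferenceFrames",
    "EnviFormatError",
    "TruncationError",
    "read_envi",
    "write_envi",
    "to_reflectance",
]

CUBE_KINDS = ("raw", "reflectance", "preprocessed")

#: ENVI numeric codes for on-disk dtypes (little-endian assumed unless the
#: header's ``byte order`` says otherwise).
_ENVI_DTYPES = {
    1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8",
    12: "u2", 13: "u4", 14: "i8", 15: "u8",
}


class EnviFormatError(ValueError):
    """Malformed or incomplete ENVI header."""


class TruncationError(EnviFormatError):
    """Binary payload size disagrees with the header's dims x dtype."""


@dataclass
class SpectralCube:
    """A hyperspectral image: ``rows x cols x bands`` plus a wavelength axis.

    Parameters
    ----------
    data
        3-D array of per-pixel intensity. Stored as float64 regardless of
        the on-disk type: derivative preprocessing amplifies quantisation,
        so narrow integer types are promoted on load.
    wavelengths
        Band centres in nanometres, strictly increasing, one per band.
    pixel_size_mm
        Side length of one pixel in millimetres (scan metadata).
    kind
        One of ``raw``, ``reflectance``, ``preprocessed``. Reflectance
        cubes must be finite everywhere (the clipping policy in
        :func:`to_reflectance` guarantees this).
    raw_unclipped
        Optional QC side channel: the unclipped reflectance values kept
        alongside a clipped ``reflectance`` cube.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    pixel_size_mm: float = 0.5
    kind: str = "raw"
    raw_unclipped: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64).ravel()
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got ndim={self.data.ndim}")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"wavelength axis length {self.wavelengths.size} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in CUBE_KINDS:
            raise ValueError(f"kind must be one of {CUBE_KINDS}, got {self.kind!r}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def pixel(self, row: int, col: int) -> np.ndarray:
        """Return one pixel's spectrum as a copy."""
        return self.data[row, col].copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralCube):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.wavelengths, other.wavelengths)
        )


@dataclass
class ReferenceFrames:
    """Dark and white reference frames for reflectance calibration.

    The push-broom geometry records references per cross-track pixel: both
    frames are ``(cols, bands)`` and are broadcast along the scan axis. A
    whole-frame average fallback of shape ``(bands,)`` is also accepted.
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.atleast_1d(np.asarray(self.dark, dtype=np.float64))
        self.white = np.atleast_1d(np.asarray(self.white, dtype=np.float64))
        if self.dark.shape != self.white.shape:
            raise ValueError("dark and white frames must share a shape")
        if self.dark.ndim not in (1, 2):
            raise ValueError("reference frames must be (bands,) or (cols, bands)")

    def usable_bands(self) -> np.ndarray:
        """Boolean per-band flag: ``white - dark`` strictly positive everywhere."""
        diff = self.white - self.dark
        if diff.ndim == 1:
            return diff > 0
        return np.all(diff > 0, axis=0)


# ---------------------------------------------------------------------------
# ENVI header parsing / writing
# ---------------------------------------------------------------------------

_HEADER_KV = re.compile(r"^\s*([^=]+?)\s*=\s*(.*)$")


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic word at top of header")
    fields: dict[str, str] = {}
    lines = text.splitlines()
    i = 1
    while i < len(lines):
        line = lines[i]
        i += 1
        m = _HEADER_KV.match(line)
        if m is None:
            continue
        key = m.group(1).strip().lower()
        value = m.group(2).strip()
        if value.startswith("{") and "}" not in value:
            # multi-line brace block
            parts = [value]
            while i < len(lines):
                parts.append(lines[i])
                if "}" in lines[i]:
                    i += 1
                    break
                i += 1
            value = " ".join(parts)
        fields[key] = value
    return fields


def _brace_list(value: str, key: str) -> list[float]:
    m = re.search(r"\{(.*)\}", value, re.S)
    if m is None:
        raise EnviFormatError(f"field {key!r} is not a brace-delimited list")
    items = [s.strip() for s in m.group(1).replace("\n", " ").split(",")]
    try:
        return [float(s) for s in items if s]
    except ValueError as exc:
        raise EnviFormatError(f"non-numeric entry in {key!r}: {exc}") from exc


def _data_path_for(header_path: Path) -> Path:
    if header_path.suffix.lower() == ".hdr":
        return header_path.with_suffix(".dat")
    return header_path.parent / (header_path.name + ".dat")


def read_envi(header_path: str | Path) -> SpectralCube:
    """Read an ENVI cube (header + flat binary) into a :class:`SpectralCube`.

    All three interleaves (BIL, BIP, BSQ) are supported and yield identical
    cubes for equivalent content. Raises :class:`EnviFormatError` naming the
    missing field for incomplete headers and :class:`TruncationError` when
    the binary payload does not match ``samples x lines x bands x itemsize``.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_header(header_path.read_text())

    def req(key: str) -> str:
        if key not in fields:
            raise EnviFormatError(f"header missing required field {key!r}")
        return fields[key]

    try:
        samples = int(req("samples"))
        lines = int(req("lines"))
        bands = int(req("bands"))
        dtype_code = int(req("data type"))
    except ValueError as exc:
        raise EnviFormatError(f"non-integer header field: {exc}") from exc
    interleave = req("interleave").lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported data type code {dtype_code}")
    byte_order = int(fields.get("byte order", "0"))
    offset = int(fields.get("header offset", "0"))
    wavelengths = np.asarray(_brace_list(req("wavelength"), "wavelength"))
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"wavelength list length {wavelengths.size} != bands {bands}"
        )

    dtype = np.dtype(("<" if byte_order == 0 else ">") + _ENVI_DTYPES[dtype_code])
    data_path = _data_path_for(header_path)
    if not data_path.exists():
        raise FileNotFoundError(data_path)
    payload = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if payload.size != expected:
        raise TruncationError(
            f"binary payload holds {payload.size} values but header declares "
            f"{lines} lines x {samples} samples x {bands} bands = {expected}"
        )
    if interleave == "bip":
        data = payload.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = payload.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        data = payload.reshape(bands, lines, samples).transpose(1, 2, 0)

    kind = fields.get("cube kind", "raw").strip().lower()
    if kind not in CUBE_KINDS:
        kind = "raw"
    pixel_size = float(fields.get("pixel size", "0.5"))
    return SpectralCube(
        data=np.ascontiguousarray(data, dtype=np.float64),
        wavelengths=wavelengths,
        pixel_size_mm=pixel_size,
        kind=kind,
    )


def write_envi(
    cube: SpectralCube,
    header_path: str | Path,
    interleave: str = "bil",
) -> None:
    """Write a cube as an ENVI header + float64 binary payload.

    The wavelength axis is written with 10 significant digits, so a
    round-trip through :func:`read_envi` is exact. Zero-sized cubes are a
    format error.
    """
    if cube.data.size == 0:
        raise EnviFormatError("refusing to write an empty (zero-sized) cube")
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    header_path = Path(header_path)
    data_path = _data_path_for(header_path)

    if interleave == "bip":
        payload = cube.data
    elif interleave == "bil":
        payload = cube.data.transpose(0, 2, 1)
    else:
        payload = cube.data.transpose(2, 0, 1)

    wl = ", ".join(f"{w:.10g}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {collagenmap hyperspectral cube}",
        f"samples = {cube.cols}",
        f"lines = {cube.rows}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 5",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"pixel size = {cube.pixel_size_mm:.10g}",
        f"cube kind = {cube.kind}",
    ]
    if cube.kind == "reflectance":
        lines.append("reflectance scale factor = 1.000000")
    lines.append("wavelength = {" + wl + "}")
    header_path.write_text("\n".join(lines) + "\n")
    np.ascontiguousarray(payload, dtype="<f8").tofile(data_path)


# ---------------------------------------------------------------------------
# Reflectance calibration
# ---------------------------------------------------------------------------

def to_reflectance(
    raw: SpectralCube,
    refs: ReferenceFrames,
    clip_max: float = 2.0,
) -> SpectralCube:
    """Flat-field raw counts to reflectance: ``R = (raw - dark)/(white - dark)``.

    Per-band, per-cross-track-pixel references are broadcast along the scan
    axis. Bands where ``white == dark`` anywhere are unusable (the division
    is undefined): they are dropped from the returned cube with a warning.
    Values are clipped to ``[0, clip_max]`` (sensor glints can exceed 1);
    the unclipped values survive in ``raw_unclipped`` for QC.
    """
    dark, white = refs.dark, refs.white
    nb = raw.n_bands
    if (dark.ndim == 1 and dark.size != nb) or (
        dark.ndim == 2 and dark.shape != (raw.cols, nb)
    ):
        raise ValueError(
            f"reference frames shaped {dark.shape} do not cover a cube with "
            f"{raw.cols} cols x {nb} bands"
        )
    usable = refs.usable_bands()
    if not np.any(usable):
        raise ValueError("no usable band: white - dark is nowhere positive")

    if dark.ndim == 1:
        d = dark[None, None, :]
        w = white[None, None, :]
    else:
        d = dark[None, :, :]
        w = white[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data - d) / (w - d)

    if not np.all(usable):
        n_bad = int(np.sum(~usable))
        warnings.warn(
            f"dropping {n_bad} band(s) with white == dark from reflectance cube",
            stacklevel=2,
        )
        refl = refl[:, :, usable]
        wavelengths = raw.wavelengths[usable]
    else:
        wavelengths = raw.wavelengths

    unclipped = refl.copy()
    refl = np.clip(refl, 0.0, clip_max)
    return SpectralCube(
        data=refl,
        wavelengths=wavelengths,
        pixel_size_mm=raw.pixel_size_mm,
        kind="reflectance",
        raw_unclipped=unclipped,
    )
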