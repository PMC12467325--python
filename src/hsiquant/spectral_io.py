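"""Hyperspectral cube data model, radiometric calibration and I/O.

A cube is a (rows, cols, bands) array with a strictly increasing wavelength
axis in nm. Cubes are read and written either as ENVI header + raw binary
(BSQ/BIL accepted on read, BSQ written) or as multi-page TIFF (one page per
band) with a plain-text wavelength sidecar, one nm value per line.

Raw sensor counts are converted to reflectance with dark and white reference
frames, R = (raw - dark) / (white - dark), and reflectance to absorbance
(optical density) with A = -log10(max(R, floor)); absorbance is the additive
quantity under Beer-Lambert stain mixing.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .exceptions import (
    CalibrationError,
    FormatError,
    MaskError,
    SpectralWindowError,
)

__all__ = [
    "SignalKind",
    "WavelengthAxis",
    "SpectralCube",
    "CalibrationFrames",
    "calibrate_reflectance",
    "reflectance_to_absorbance",
    "crop_spectral_window",
    "mean_spectrum",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
]

#: Default acquisition grid: 500-1000 nm at 5 nm (101 bands), a commodity
#: VIS-NIR sampling.
DEFAULT_WAVELENGTHS = np.arange(500.0, 1000.0 + 2.5, 5.0)

REFLECTANCE_CEILING = 1.5  # tolerates specular pixels without unbounded values


class SignalKind(str, Enum):
    RAW = "RAW"
    REFLECTANCE = "REFLECTANCE"
    ABSORBANCE = "ABSORBANCE"


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing wavelength grid in nm, within the 400-1100 nm VIS-NIR span."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength axis must be 1-D with at least 2 values")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if values[0] < 400.0 or values[-1] > 1100.0:
            raise ValueError("wavelengths must lie within [400, 1100] nm")

    def __len__(self) -> int:
        return int(self.values.size)

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of bands with lo <= lambda <= hi (inclusive both ends)."""
        return (self.values >= lo) & (self.values <= hi)


@dataclass
class SpectralCube:
    """Calibrated (or raw) image cube over (row, col, wavelength)."""

    data: np.ndarray
    axis: WavelengthAxis
    signal_kind: SignalKind = SignalKind.RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-dimensional (rows, cols, bands)")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but axis has {len(self.axis)}"
            )
        self.signal_kind = SignalKind(self.signal_kind)
        if self.signal_kind is SignalKind.REFLECTANCE:
            if self.data.min() < -1e-9 or self.data.max() > REFLECTANCE_CEILING + 1e-9:
                raise ValueError("reflectance values must lie in [0, 1.5]")
        elif self.signal_kind is SignalKind.ABSORBANCE:
            if self.data.min() < -1e-9:
                raise ValueError("absorbance values must be non-negative")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def pixels(self) -> np.ndarray:
        """View of the cube as an (n_pixels, n_bands) spectrum matrix."""
        return self.data.reshape(-1, self.n_bands)


@dataclass
class CalibrationFrames:
    """Dark and white reference frames, same shape as the raw cube."""

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ValueError("dark and white frames must have identical shapes")


def calibrate_reflectance(
    raw: np.ndarray, frames: CalibrationFrames, axis: WavelengthAxis
) -> SpectralCube:
    """Convert raw counts to reflectance: R = (raw - dark) / (white - dark).

    The result is clipped to [0, 1.5]. Any band where white - dark vanishes
    somewhere makes the calibration undefined and raises
    :class:`CalibrationError` naming that band.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != frames.dark.shape:
        raise CalibrationError("raw cube and calibration frames have different shapes")
    denom = frames.white - frames.dark
    bad = np.nonzero(np.any(denom <= 0, axis=(0, 1)))[0]
    if bad.size:
        raise CalibrationError(
            f"white - dark is not positive everywhere in band {int(bad[0])} "
            f"({axis.values[int(bad[0])]:g} nm)"
        )
    refl = np.clip((raw - frames.dark) / denom, 0.0, REFLECTANCE_CEILING)
    return SpectralCube(refl, axis, SignalKind.REFLECTANCE, meta={"calibrated": True})


def reflectance_to_absorbance(cube: SpectralCube, floor: float = 1e-4) -> SpectralCube:
    """Optical density A = -log10(max(R, floor)); requires a REFLECTANCE cube."""
    if cube.signal_kind is not SignalKind.REFLECTANCE:
        raise ValueError("reflectance_to_absorbance requires a REFLECTANCE cube")
    if floor <= 0:
        raise ValueError("floor must be positive")
    od = -np.log10(np.maximum(cube.data, floor))
    od = np.maximum(od, 0.0)  # R slightly above 1 (specular) clamps to zero OD
    return SpectralCube(od, cube.axis, SignalKind.ABSORBANCE, meta=dict(cube.meta))


def crop_spectral_window(cube: SpectralCube, lo: float, hi: float) -> SpectralCube:
    """Keep bands with lo <= lambda <= hi, inclusive at both ends."""
    if lo >= hi:
        raise SpectralWindowError("window low bound must be below high bound")
    mask = cube.axis.window_mask(lo, hi)
    if not mask.any():
        raise SpectralWindowError(
            f"window [{lo:g}, {hi:g}] nm does not overlap the wavelength axis"
        )
    return SpectralCube(
        cube.data[:, :, mask],
        WavelengthAxis(cube.axis.values[mask]),
        cube.signal_kind,
        meta=dict(cube.meta),
    )


def mean_spectrum(cube: SpectralCube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean spectrum over the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.spatial_shape:
        raise MaskError("mask shape does not match the cube's spatial shape")
    if not mask.any():
        raise MaskError("mask selects no pixels")
    return cube.data[mask].mean(axis=0)


# ---------------------------------------------------------------------------
# ENVI header + raw binary I/O (minimal dialect: BSQ/BIL read, BSQ write)
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: "<f4", 5: "<f8"}
_ENVI_CODES = {np.dtype("<f4"): 4, np.dtype("<f8"): 5}


def _parse_envi_header(text: str) -> dict:
    """Parse the subset of the ENVI header syntax needed here."""
    fields: dict[str, str] = {}
    body = re.sub(r"^ENVI\s*", "", text.strip())
    # fold { ... } blocks onto one line
    body = re.sub(r"\{([^}]*)\}", lambda m: "{" + " ".join(m.group(1).split()) + "}", body, flags=re.S)
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _write_envi(cube: SpectralCube, path: Path) -> None:
    hdr = path.with_suffix(".hdr")
    data = np.ascontiguousarray(np.transpose(cube.data, (2, 0, 1)))  # BSQ
    code = _ENVI_CODES[np.dtype("<f8")]
    data.astype("<f8").tofile(path)
    wl = ", ".join(f"{v:.6f}" for v in cube.axis.values)
    lines = [
        "ENVI",
        f"samples = {cube.data.shape[1]}",
        f"lines = {cube.data.shape[0]}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = nm",
        f"signal kind = {cube.signal_kind.value}",
        "wavelength = {" + wl + "}",
    ]
    hdr.write_text("\n".join(lines) + "\n")


def _read_envi(path: Path) -> SpectralCube:
    hdr = path.with_suffix(".hdr")
    if not hdr.exists():
        raise FormatError(f"missing ENVI header {hdr}")
    fields = _parse_envi_header(hdr.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header {hdr} lacks required field {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError(f"ENVI header {hdr} declares no wavelengths")
    wl_text = fields["wavelength"].strip("{} ")
    wavelengths = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise FormatError(
            f"ENVI header declares {bands} bands but {wavelengths.size} wavelengths"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    flat = np.fromfile(path, dtype=_ENVI_DTYPES[dtype_code])
    if flat.size != samples * lines * bands:
        raise FormatError(f"ENVI file {path} size does not match header dimensions")
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:
        raise FormatError(f"unsupported ENVI interleave '{interleave}'")
    kind = SignalKind(fields.get("signal kind", "RAW"))
    return SpectralCube(np.ascontiguousarray(data, dtype=float), WavelengthAxis(wavelengths), kind)


# ---------------------------------------------------------------------------
# Multi-page TIFF + wavelength sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".wavelengths.txt")


def _write_tiff(cube: SpectralCube, path: Path) -> None:
    pages = np.transpose(cube.data, (2, 0, 1)).astype("<f8")
    tifffile.imwrite(
        path,
        pages,
        photometric="minisblack",
        description=json.dumps({"signal_kind": cube.signal_kind.value}),
    )
    _sidecar_path(path).write_text(
        "".join(f"{v:.6f}\n" for v in cube.axis.values)
    )


def _read_tiff(path: Path) -> SpectralCube:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing wavelength sidecar {sidecar}")
    wavelengths = np.array(
        [float(line) for line in sidecar.read_text().split() if line.strip()]
    )
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or "{}"
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != wavelengths.size:
        raise FormatError(
            f"TIFF has {pages.shape[0]} pages but sidecar lists {wavelengths.size} wavelengths"
        )
    try:
        kind = SignalKind(json.loads(desc).get("signal_kind", "RAW"))
    except (json.JSONDecodeError, ValueError):
        kind = SignalKind.RAW
    data = np.ascontiguousarray(np.transpose(pages, (1, 2, 0)), dtype=float)
    return SpectralCube(data, WavelengthAxis(wavelengths), kind)


def write_cube(cube: SpectralCube, path: str | Path, format: str | None = None) -> Path:
    """Write a cube as ENVI (``.dat`` + ``.hdr``) or multi-page TIFF + sidecar."""
    path = Path(path)
    fmt = (format or _infer_format(path)).upper()
    if fmt == "ENVI":
        _write_envi(cube, path)
    elif fmt == "TIFF":
        _write_tiff(cube, path)
    else:
        raise FormatError(f"unknown cube format '{fmt}'")
    return path


def read_cube(path: str | Path, format: str | None = None) -> SpectralCube:
    """Read a cube previously written by :func:`write_cube` (or compatible files)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such cube file: {path}")
    fmt = (format or _infer_format(path)).upper()
    if fmt == "ENVI":
        return _read_envi(path)
    if fmt == "TIFF":
        return _read_tiff(path)
    raise FormatError(f"unknown cube format '{fmt}'")


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return "TIFF"
    return "ENVI"


# ---------------------------------------------------------------------------
# Boolean masks as 8-bit PNG (nonzero = true)
# ---------------------------------------------------------------------------


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0
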