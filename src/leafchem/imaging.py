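"""Hyperspectral cube I/O, NDVI computation, and leaf segmentation.

A leaf acquisition is a rows x cols x bands reflectance cube on a known
wavelength grid. Leaf pixels are separated from the imaging stage by the
normalized difference vegetation index,

    NDVI = (r_nir - r_red) / (r_nir + r_red),

with r_nir and r_red read from the channels nearest 780 nm and 660 nm;
pixels with NDVI > 0 are leaf. The mean spectrum over the leaf mask is the
per-sample observation used by all downstream modeling.

Cubes are stored in the ENVI container: a flat binary file plus a plain-text
header declaring shape, interleave (BSQ/BIL/BIP), data type, byte order and
the wavelength list. The codec here round-trips all three interleaves
bit-exactly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, EmptySegmentationError, FormatError

__all__ = [
    "HyperspectralCube",
    "NDVIMap",
    "LeafMask",
    "read_envi_cube",
    "write_envi_cube",
    "ndvi_map",
    "segment_leaf",
    "extract_mean_spectrum",
]

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperspectralCube:
    """rows x cols x bands reflectance in [0, 1] on an ascending nm grid."""

    reflectance: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 3:
            raise ConfigurationError("reflectance must be rows x cols x bands")
        if self.reflectance.shape[2] != self.wavelengths.size:
            raise ConfigurationError("band count must match wavelength count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        if np.any(self.reflectance < 0):
            raise ConfigurationError("negative reflectance after ingestion")

    @property
    def shape(self) -> tuple:
        return self.reflectance.shape

    def nearest_band(self, nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - nm)))


@dataclass
class NDVIMap:
    """Per-pixel NDVI plus the channel indices it was computed from."""

    values: np.ndarray
    nir_band_index: int
    red_band_index: int


@dataclass
class LeafMask:
    """Boolean leaf-pixel mask."""

    keep: np.ndarray

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.keep.sum())

    def to_ascii(self, path) -> None:
        """Write the mask as rows of 0/1 characters for quick inspection."""
        lines = ["".join("1" if v else "0" for v in row) for row in self.keep]
        Path(path).write_text("\n".join(lines) + "\n")


def write_envi_cube(cube: HyperspectralCube, header_path, interleave: str = "bil",
                    dtype=np.float64) -> Path:
    """Write an ENVI header/binary pair; returns the binary path.

    The binary file sits next to the header with a ``.dat`` suffix.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    header_path = Path(header_path)
    data_path = header_path.with_suffix(".dat")
    arr = cube.reflectance.astype(dtype)
    rows, cols, bands = arr.shape
    if interleave == "bip":        # (lines, samples, bands)
        ordered = arr
    elif interleave == "bil":      # (lines, bands, samples)
        ordered = arr.transpose(0, 2, 1)
    else:                          # bsq: (bands, lines, samples)
        ordered = arr.transpose(2, 0, 1)
    ordered.tofile(data_path)

    wl = ", ".join(f"{w:.17g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    return data_path


def _parse_envi_header(text: str) -> dict:
    # collapse { ... } blocks (possibly multi-line) before splitting fields
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi_cube(header_path) -> HyperspectralCube:
    """Read an ENVI header + binary pair into a :class:`HyperspectralCube`.

    Accepts BSQ, BIL and BIP interleaves and the numeric ENVI data types;
    negative reflectance (e.g. sensor offsets) is clipped to zero on ingest.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"missing ENVI header {header_path}")
    fields = _parse_envi_header(header_path.read_text())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
        offset = int(fields.get("header offset", 0))
        byte_order = int(fields.get("byte order", 0))
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("ENVI header lacks wavelength metadata")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise FormatError("wavelength list length disagrees with band count")
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    if byte_order == 1:
        dtype = dtype.newbyteorder(">")

    data_path = None
    for cand in (header_path.with_suffix(".dat"), header_path.with_suffix(".img"),
                 header_path.with_suffix("")):
        if cand.exists() and cand != header_path:
            data_path = cand
            break
    if data_path is None:
        raise FormatError(f"no binary companion found for {header_path}")

    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    if raw.size != rows * cols * bands:
        raise FormatError(
            f"binary size {raw.size} != lines*samples*bands {rows * cols * bands}"
        )
    if interleave == "bip":
        arr = raw.reshape(rows, cols, bands)
    elif interleave == "bil":
        arr = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":
        arr = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    arr = np.maximum(arr.astype(float), 0.0)
    return HyperspectralCube(arr, wavelengths)


def ndvi_map(cube: HyperspectralCube, nir_nm: float = 780.0, red_nm: float = 660.0) -> NDVIMap:
    """Per-pixel NDVI from the channels nearest the requested wavelengths.

    Pixels where r_nir + r_red == 0 (fully dark) are defined as NDVI 0,
    i.e. background under the standard NDVI > 0 leaf rule.
    """
    if cube.wavelengths.size < 2:
        raise ConfigurationError("NDVI needs at least two bands")
    for nm in (nir_nm, red_nm):
        if not (cube.wavelengths[0] <= nm <= cube.wavelengths[-1]):
            warnings.warn(
                f"{nm} nm outside the grid; using nearest channel", stacklevel=2
            )
    i_nir = cube.nearest_band(nir_nm)
    i_red = cube.nearest_band(red_nm)
    nir = cube.reflectance[:, :, i_nir]
    red = cube.reflectance[:, :, i_red]
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), 0.0)
    return NDVIMap(values, i_nir, i_red)


def segment_leaf(ndvi: NDVIMap, threshold: float = 0.0) -> LeafMask:
    """Leaf mask by strict thresholding: keep pixels with NDVI > threshold."""
    return LeafMask(ndvi.values > threshold)


def extract_mean_spectrum(cube: HyperspectralCube, mask: LeafMask) -> np.ndarray:
    """Per-band arithmetic mean reflectance over the masked pixels."""
    if mask.keep.shape != cube.reflectance.shape[:2]:
        raise ConfigurationError("mask shape must match the cube's spatial shape")
    if mask.n_pixels == 0:
        raise EmptySegmentationError("no leaf pixels; segmentation failed")
    return cube.reflectance[mask.keep].mean(axis=0)
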