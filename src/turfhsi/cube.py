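"""Hyperspectral reflectance cubes: ENVI-style I/O, calibration, ROIs, pseudo-RGB.

A :class:`ReflectanceCube` is the substrate every pipeline stage reads: a
``rows x cols x n_bands`` float array of surface reflectance together with the
per-band centre wavelengths in nanometres.  Cubes are exchanged on disk as an
ENVI-style text header (``.hdr``) plus a raw binary array in band-sequential
(BSQ) or band-interleaved-by-line (BIL) order, the native interchange format
of the portable VNIR instrument family this package targets (204 bands over
400-1000 nm, 512 x 512 spatial frames).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ReflectanceCube",
    "RegionOfInterest",
    "PseudoRGBImage",
    "CubeFormatError",
    "CalibrationError",
    "DEFAULT_RGB_BANDS",
    "load_cube",
    "save_cube",
    "calibrate_reflectance",
    "band_for_wavelength",
    "render_pseudo_rgb",
    "extract_roi",
]

#: Band triplet used for (R, G, B) pseudo-colour composites; 0-based indices
#: into the 204-band VNIR stack (~602, 549 and 452 nm).
DEFAULT_RGB_BANDS = (70, 52, 19)

#: Reflectance values above this ceiling after white-panel division are
#: treated as specular glints and clamped.
DEFAULT_REFLECTANCE_CEILING = 1.5


class CubeFormatError(ValueError):
    """Header/binary mismatch or unreadable cube container."""


class CalibrationError(ValueError):
    """White-reference calibration cannot proceed (e.g. zero panel mean)."""


@dataclass
class ReflectanceCube:
    """A VNIR reflectance cube with per-band wavelengths.

    Parameters
    ----------
    data
        ``(rows, cols, n_bands)`` float array. Dimensionless reflectance,
        nominally in ``[0, ~1.5]`` after calibration.
    wavelengths
        Strictly increasing band-centre wavelengths in nm, length ``n_bands``.
    source_id
        Free-text provenance label.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise CubeFormatError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.data.shape[2] < 3:
            raise CubeFormatError("cube needs at least 3 bands")
        if self.wavelengths.shape != (self.data.shape[2],):
            raise CubeFormatError(
                f"wavelength vector length {self.wavelengths.size} does not "
                f"match band count {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise CubeFormatError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class RegionOfInterest:
    """Rectangle or polygon region in 0-based ``(row, col)`` pixel coordinates.

    Rectangles are given by two opposite corners (inclusive). Polygons need at
    least three vertices and are closed implicitly; pixel membership follows
    the even-odd rule evaluated at pixel centres.
    """

    shape_kind: str  # "rectangle" | "polygon"
    vertices: list[tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape_kind not in ("rectangle", "polygon"):
            raise ValueError(f"unknown ROI kind {self.shape_kind!r}")
        self.vertices = [(float(r), float(c)) for r, c in self.vertices]
        if self.shape_kind == "rectangle" and len(self.vertices) != 2:
            raise ValueError("rectangle ROI needs exactly 2 corner vertices")
        if self.shape_kind == "polygon" and len(self.vertices) < 3:
            raise ValueError("polygon ROI needs at least 3 vertices")

    @classmethod
    def rectangle(
        cls, row0: int, col0: int, row1: int, col1: int, label: str = ""
    ) -> "RegionOfInterest":
        return cls("rectangle", [(row0, col0), (row1, col1)], label=label)

    @classmethod
    def full_frame(cls, rows: int, cols: int, label: str = "") -> "RegionOfInterest":
        return cls.rectangle(0, 0, rows - 1, cols - 1, label=label)

    def membership_mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean frame mask of pixels inside the region."""
        rows, cols = frame_shape
        verts = np.asarray(self.vertices, dtype=float)
        if np.any(verts[:, 0] < 0) or np.any(verts[:, 1] < 0) or np.any(
            verts[:, 0] > rows - 1
        ) or np.any(verts[:, 1] > cols - 1):
            raise ValueError("ROI vertices outside cube bounds")
        mask = np.zeros(frame_shape, dtype=bool)
        if self.shape_kind == "rectangle":
            (r0, c0), (r1, c1) = self.vertices
            r0, r1 = sorted((int(round(r0)), int(round(r1))))
            c0, c1 = sorted((int(round(c0)), int(round(c1))))
            mask[r0 : r1 + 1, c0 : c1 + 1] = True
        else:
            rr, cc = np.mgrid[0:rows, 0:cols]
            py = rr.ravel().astype(float)
            px = cc.ravel().astype(float)
            inside = np.zeros(py.size, dtype=bool)
            # even-odd crossing count at pixel centres (implicitly closed)
            n = len(self.vertices)
            for i in range(n):
                y1, x1 = verts[i]
                y2, x2 = verts[(i + 1) % n]
                straddles = (y1 > py) != (y2 > py)
                with np.errstate(divide="ignore", invalid="ignore"):
                    x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                inside ^= straddles & (px < x_cross)
            mask = inside.reshape(frame_shape)
        return mask


@dataclass
class PseudoRGBImage:
    """8-bit colour composite rendered from three cube bands."""

    data: np.ndarray  # (rows, cols, 3) uint8
    band_triplet: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("pseudo-RGB image must have shape (rows, cols, 3)")


# ---------------------------------------------------------------------------
# ENVI-style container
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _parse_envi_header(header_path: Path) -> dict:
    text = header_path.read_text()
    # collapse { ... } blocks (possibly multi-line) onto their key line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def load_cube(header_path, data_path=None) -> ReflectanceCube:
    """Read an ENVI-style header + raw binary cube.

    If the header carries no wavelength list, band centres are assigned
    linearly over 400-1000 nm, the nominal span of the VNIR instrument.

    Parameters
    ----------
    header_path
        Path to the ``.hdr`` text header.
    data_path
        Path to the binary cube; defaults to the header path with its
        ``.hdr`` suffix removed (or swapped for ``.raw``).
    """
    header_path = Path(header_path)
    if data_path is None:
        stem = header_path.with_suffix("")
        data_path = stem if stem.exists() else header_path.with_suffix(".raw")
    data_path = Path(data_path)
    fields = _parse_envi_header(header_path)
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise CubeFormatError(f"header missing required field: {exc}") from exc
    dtype_code = int(fields.get("data type", 4))
    if dtype_code not in _ENVI_DTYPES:
        raise CubeFormatError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    raw = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise CubeFormatError(
            f"binary cube holds {raw.size} values; header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise CubeFormatError(f"unreadable interleave {interleave!r}")
    wl_text = fields.get("wavelength")
    if wl_text:
        wavelengths = np.array(
            [float(v) for v in wl_text.strip("{} ").split(",") if v.strip()]
        )
        if wavelengths.size != bands:
            raise CubeFormatError("wavelength list length disagrees with band count")
    else:
        wavelengths = np.linspace(400.0, 1000.0, bands)
    return ReflectanceCube(
        data=np.ascontiguousarray(data, dtype=np.float32),
        wavelengths=wavelengths,
        source_id=str(data_path),
    )


def save_cube(
    cube: ReflectanceCube, header_path, data_path=None, interleave: str = "bsq"
) -> tuple[Path, Path]:
    """Write the cube as ENVI-style header + float32 binary (BSQ or BIL)."""
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".raw")
    data_path = Path(data_path)
    interleave = interleave.lower()
    rows, cols, bands = cube.shape
    arr = cube.data.astype(np.float32)
    if interleave == "bsq":
        flat = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = arr.transpose(0, 2, 1)
    else:
        raise CubeFormatError(f"unsupported interleave for writing: {interleave!r}")
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    np.ascontiguousarray(flat).tofile(data_path)
    return header_path, data_path


# ---------------------------------------------------------------------------
# Calibration and band lookup
# ---------------------------------------------------------------------------


def calibrate_reflectance(
    raw: ReflectanceCube,
    white_region: RegionOfInterest,
    ceiling: float = DEFAULT_REFLECTANCE_CEILING,
) -> ReflectanceCube:
    """Convert raw counts to reflectance via a white reference panel.

    Each band is divided by the mean raw signal over the white-panel region
    (a ~99% reflectance BaSO4 panel placed in the frame during capture).
    Values above ``ceiling`` (specular glints) are clamped; negatives are
    clipped to zero.
    """
    mask = white_region.membership_mask(raw.frame_shape)
    if not mask.any():
        raise CalibrationError("white-reference region selects no pixels")
    panel = raw.data[mask].mean(axis=0)  # per-band mean, shape (n_bands,)
    bad = np.flatnonzero(panel <= 0)
    if bad.size:
        raise CalibrationError(
            f"white panel mean is zero or negative in band(s) {bad[:5].tolist()}"
        )
    refl = raw.data / panel[None, None, :]
    refl = np.clip(refl, 0.0, ceiling)
    return ReflectanceCube(refl, raw.wavelengths, source_id=raw.source_id)


def band_for_wavelength(cube: ReflectanceCube, target_nm: float) -> int:
    """Index of the band whose centre is nearest ``target_nm``.

    Ties between two equidistant neighbours resolve to the lower index. The
    target must fall within the sensed range plus half the mean band spacing.
    """
    wl = cube.wavelengths
    half_step = float(np.mean(np.diff(wl))) / 2.0 if wl.size > 1 else 0.0
    if target_nm < wl[0] - half_step or target_nm > wl[-1] + half_step:
        raise ValueError(
            f"{target_nm} nm outside sensed range [{wl[0]}, {wl[-1]}] nm"
        )
    # argmin returns the first (lowest) index on exact ties
    return int(np.argmin(np.abs(wl - target_nm)))


# ---------------------------------------------------------------------------
# Pseudo-RGB rendering and ROI extraction
# ---------------------------------------------------------------------------


def render_pseudo_rgb(
    cube: ReflectanceCube,
    band_triplet: Sequence[int] = DEFAULT_RGB_BANDS,
    pct_low: float = 2.0,
    pct_high: float = 98.0,
) -> PseudoRGBImage:
    """Render a percentile-stretched 8-bit composite from three bands.

    Each channel is stretched linearly so its ``pct_low`` percentile maps to 0
    and its ``pct_high`` percentile to 255, then clipped. A constant channel
    maps to all zeros. The stretch absorbs any monotone affine rescaling of a
    channel's reflectance, so the composite is calibration-robust.
    """
    if not (0 <= pct_low < pct_high <= 100):
        raise ValueError("need 0 <= pct_low < pct_high <= 100")
    triplet = tuple(int(b) for b in band_triplet)
    if len(triplet) != 3 or any(b < 0 or b >= cube.n_bands for b in triplet):
        raise ValueError(f"band triplet {triplet} invalid for {cube.n_bands} bands")
    out = np.zeros((*cube.frame_shape, 3), dtype=np.uint8)
    for ch, band in enumerate(triplet):
        plane = cube.data[:, :, band].astype(np.float64)
        lo, hi = np.percentile(plane, [pct_low, pct_high])
        if hi <= lo:
            continue  # degenerate channel stays 0
        stretched = np.clip((plane - lo) / (hi - lo), 0.0, 1.0)
        out[:, :, ch] = np.round(stretched * 255).astype(np.uint8)
    return PseudoRGBImage(out, triplet)


def extract_roi(
    cube: ReflectanceCube, roi: RegionOfInterest
) -> tuple[np.ndarray, np.ndarray]:
    """Pull the spectra of all pixels inside an ROI.

    Returns
    -------
    spectra
        ``(n_pixels, n_bands)`` array, pixels in row-major frame order.
    coords
        ``(n_pixels, 2)`` integer ``(row, col)`` coordinates, so downstream
        masks can be mapped back into the image frame.
    """
    mask = roi.membership_mask(cube.frame_shape)
    if not mask.any():
        raise ValueError(f"ROI {roi.label!r} selects no pixels")
    coords = np.argwhere(mask)
    spectra = cube.data[mask]
    return spectra, coords
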