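"""Vegetation indices on reflectance cubes: computation, normalisation,
threshold masking, and per-ROI summaries.

Eleven indices are supported, spanning the classic broadband family (NDVI,
EVI, GNDVI), red-edge indices (RE-NDVI, mND705, VOG-REI1), the green
chlorophyll index (GCI), and the simple-ratio family (SRI, PSSRa/b/c).
Generic band names resolve to fixed wavelength anchors (NIR = 800 nm,
Red = 670 nm, Green = 550 nm, Blue = 450 nm, red edge = 720 nm; all
configurable), and explicit ``R_xxx`` terms resolve to the nearest sensed
band. Pixels whose denominator magnitude falls below 1e-9 are marked invalid
and excluded from masks and statistics rather than clamped, keeping summary
statistics unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .cube import ReflectanceCube, band_for_wavelength
from .masks import VegetationMask

__all__ = [
    "IndexDefinition",
    "IndexMap",
    "INDEX_DEFINITIONS",
    "FIVE_QUALITY_INDICES",
    "DEFAULT_ANCHORS_NM",
    "compute_index",
    "normalize_index",
    "index_threshold_mask",
    "combine_index_masks",
    "roi_summary",
]

#: Wavelength anchors (nm) for generic band names in the formulas.
DEFAULT_ANCHORS_NM = {
    "NIR": 800.0,
    "Red": 670.0,
    "Green": 550.0,
    "Blue": 450.0,
    "RE": 720.0,
}

#: The five indices whose per-genotype ranks feed the quality half of the
#: Combined Ranking Score.
FIVE_QUALITY_INDICES = ("PSSRb", "NDVI", "GCI", "RE-NDVI", "VOG-REI1")

DENOM_EPS = 1e-9


@dataclass(frozen=True)
class IndexDefinition:
    """One vegetation index: required wavelengths and the two-part formula.

    ``numerator`` and ``denominator`` are evaluated on a mapping from band
    role to per-pixel reflectance; the index is numerator / denominator, plus
    ``offset`` (used by GCI's ``NIR/Green - 1``).
    """

    name: str
    wavelengths_nm: tuple[tuple[str, float], ...]  # (role, nm) pairs
    numerator: Callable[[Mapping[str, np.ndarray]], np.ndarray]
    denominator: Callable[[Mapping[str, np.ndarray]], np.ndarray]
    valid_range: tuple[float, float]
    offset: float = 0.0
    ratio_form: bool = True  # invariant to positive scaling of reflectance

    def required_nm(self) -> dict[str, float]:
        return dict(self.wavelengths_nm)


def _defs() -> dict[str, IndexDefinition]:
    A = DEFAULT_ANCHORS_NM
    d: dict[str, IndexDefinition] = {}

    def add(name, wl, num, den, rng, offset=0.0, ratio_form=True):
        d[name] = IndexDefinition(
            name, tuple(wl.items()), num, den, rng, offset, ratio_form
        )

    add(
        "NDVI",
        {"NIR": A["NIR"], "Red": A["Red"]},
        lambda b: b["NIR"] - b["Red"],
        lambda b: b["NIR"] + b["Red"],
        (-1.0, 1.0),
    )
    add(
        "EVI",
        {"NIR": A["NIR"], "Red": A["Red"], "Blue": A["Blue"]},
        lambda b: 2.5 * (b["NIR"] - b["Red"]),
        lambda b: b["NIR"] + 6.0 * b["Red"] - 7.5 * b["Blue"] + 1.0,
        (-1.0, 1.0),
        ratio_form=False,  # the +1 soil term breaks scale invariance
    )
    add(
        "GNDVI",
        {"NIR": A["NIR"], "Green": A["Green"]},
        lambda b: b["NIR"] - b["Green"],
        lambda b: b["NIR"] + b["Green"],
        (-1.0, 1.0),
    )
    add(
        "RE-NDVI",
        {"NIR": A["NIR"], "RE": A["RE"]},
        lambda b: b["NIR"] - b["RE"],
        lambda b: b["NIR"] + b["RE"],
        (-1.0, 1.0),
    )
    add(
        "mND705",
        {"R750": 750.0, "R705": 705.0, "R445": 445.0},
        lambda b: b["R750"] - b["R705"],
        lambda b: b["R750"] + b["R705"] - 2.0 * b["R445"],
        (-1.0, 1.0),
    )
    add(
        "GCI",
        {"NIR": A["NIR"], "Green": A["Green"]},
        lambda b: b["NIR"],
        lambda b: b["Green"],
        (0.0, 10.0),
        offset=-1.0,
    )
    add(
        "VOG-REI1",
        {"R740": 740.0, "R720": 720.0},
        lambda b: b["R740"],
        lambda b: b["R720"],
        (0.0, 5.0),
    )
    add(
        "SRI",
        {"NIR": A["NIR"], "Red": A["Red"]},
        lambda b: b["NIR"],
        lambda b: b["Red"],
        (0.0, 20.0),
    )
    for suffix, nm in (("a", 675.0), ("b", 650.0), ("c", 500.0)):
        add(
            f"PSSR{suffix}",
            {"R800": 800.0, f"R{int(nm)}": nm},
            lambda b: b["R800"],
            (lambda key: (lambda b: b[key]))(f"R{int(nm)}"),
            (0.0, 20.0),
        )
    return d


INDEX_DEFINITIONS: dict[str, IndexDefinition] = _defs()


@dataclass
class IndexMap:
    """Per-pixel values of one index over the image frame.

    ``valid`` is False where the pixel is masked out or the formula's
    denominator is near zero; ``values`` are finite wherever valid.
    """

    values: np.ndarray
    definition: IndexDefinition
    valid: np.ndarray
    normalized: bool = False

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def compute_index(
    cube: ReflectanceCube,
    definition: IndexDefinition | str,
    mask: Optional[VegetationMask] = None,
) -> IndexMap:
    """Evaluate one index per retained pixel using nearest-band reflectances."""
    if isinstance(definition, str):
        definition = INDEX_DEFINITIONS[definition]
    bands: dict[str, np.ndarray] = {}
    for role, nm in definition.wavelengths_nm:
        idx = band_for_wavelength(cube, nm)  # raises on unresolvable wavelength
        bands[role] = cube.data[:, :, idx].astype(np.float64)
    retained = (
        mask.mask if mask is not None else np.ones(cube.frame_shape, dtype=bool)
    )
    num = definition.numerator(bands)
    den = definition.denominator(bands)
    valid = retained & (np.abs(den) >= DENOM_EPS)
    values = np.zeros(cube.frame_shape, dtype=np.float64)
    np.divide(num, den, out=values, where=valid)
    values += definition.offset
    values[~valid] = np.nan
    return IndexMap(values=values, definition=definition, valid=valid)


def normalize_index(index_map: IndexMap, mode: str = "theoretical") -> IndexMap:
    """Map index values into [0, 1].

    ``theoretical`` rescales by the definition's valid range (clipping
    out-of-range values); ``empirical`` rescales by the observed min/max over
    valid pixels. A constant map normalises to 0.5 everywhere.
    """
    if mode not in ("theoretical", "empirical"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    vals = index_map.valid_values()
    if vals.size == 0:
        raise ValueError("no valid pixels to normalise")
    if mode == "theoretical":
        lo, hi = index_map.definition.valid_range
    else:
        lo, hi = float(vals.min()), float(vals.max())
    out = np.full_like(index_map.values, np.nan)
    if hi <= lo:
        out[index_map.valid] = 0.5
    else:
        out[index_map.valid] = np.clip(
            (index_map.values[index_map.valid] - lo) / (hi - lo), 0.0, 1.0
        )
    return IndexMap(
        values=out,
        definition=index_map.definition,
        valid=index_map.valid.copy(),
        normalized=True,
    )


def index_threshold_mask(
    index_map: IndexMap, threshold: float, direction: str = "ge"
) -> VegetationMask:
    """Binary mask of valid pixels passing the comparison with ``threshold``."""
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    with np.errstate(invalid="ignore"):
        cmp = (
            index_map.values >= threshold
            if direction == "ge"
            else index_map.values <= threshold
        )
    return VegetationMask(index_map.valid & cmp, provenance="index-filtered")


def combine_index_masks(
    masks: Sequence[VegetationMask],
    enabled: Optional[Sequence[bool]] = None,
    fallback: Optional[VegetationMask] = None,
) -> VegetationMask:
    """Intersect all enabled index masks.

    With zero enabled masks the upstream refinement mask (``fallback``) passes
    through unchanged.
    """
    if enabled is None:
        enabled = [True] * len(masks)
    if len(enabled) != len(masks):
        raise ValueError("enabled flags must match mask list length")
    active = [m for m, on in zip(masks, enabled) if on]
    if not active:
        if fallback is None:
            raise ValueError("no enabled masks and no fallback mask supplied")
        return VegetationMask(fallback.mask.copy(), provenance=fallback.provenance)
    shape = active[0].shape
    out = np.ones(shape, dtype=bool)
    for m in active:
        if m.shape != shape:
            raise ValueError("index masks have mismatched shapes")
        out &= m.mask
    return VegetationMask(out, provenance="index-filtered")


def roi_summary(
    cube: ReflectanceCube,
    final_mask: VegetationMask,
    index_maps: Mapping[str, IndexMap],
) -> dict:
    """Aggregate one ROI: vegetation pixel count, per-index means, mean
    spectrum over retained valid pixels. Empty masks yield count 0 and NaN
    means (missing data is encoded, never thrown)."""
    retained = final_mask.mask
    count = int(retained.sum())
    index_means: dict[str, float] = {}
    for name, imap in index_maps.items():
        sel = retained & imap.valid
        index_means[name] = float(imap.values[sel].mean()) if sel.any() else float("nan")
    if count:
        mean_spectrum = cube.data[retained].mean(axis=0).astype(np.float64)
    else:
        mean_spectrum = np.full(cube.n_bands, np.nan)
    return {
        "pixel_count": count,
        "index_means": index_means,
        "mean_spectrum": mean_spectrum,
    }
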