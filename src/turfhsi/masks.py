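"""Vegetation masks and pseudo-RGB colour refinement.

The classifier mask from the segmentation stage is refined by intersecting it
with a colour-similarity mask built on the pseudo-RGB composite: a pixel
survives only if it is both spectrally classified as vegetation and visually
close to a sampled healthy-vegetation colour. All non-retained pixels of the
cube are then zeroed so later stages see only validated vegetation spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .cube import PseudoRGBImage, ReflectanceCube

__all__ = [
    "ColorTarget",
    "VegetationMask",
    "color_similarity_mask",
    "intersect_masks",
    "apply_mask_to_cube",
    "mask_overlay_report",
    "save_mask_png",
    "load_mask_png",
]

OVERLAY_CATEGORIES = ("neither", "color_only", "rfc_only", "intersection")


@dataclass
class ColorTarget:
    """An RGB triplet sampled from healthy vegetation, with a match tolerance.

    ``tolerance`` is a fraction of the full 8-bit scale per channel (default
    0.30, i.e. +/-76.5 counts). ``relative=True`` switches to a tolerance
    proportional to the target value itself; the absolute mode is the default
    because relative bands collapse to zero width at dark targets.
    """

    rgb: tuple[int, int, int]
    tolerance: float = 0.30
    relative: bool = False

    def __post_init__(self) -> None:
        self.rgb = tuple(int(v) for v in self.rgb)
        if len(self.rgb) != 3 or any(v < 0 or v > 255 for v in self.rgb):
            raise ValueError(f"rgb triplet {self.rgb} outside [0, 255]")
        if not 0.0 <= self.tolerance <= 1.0:
            raise ValueError("tolerance must lie in [0, 1]")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-channel (low, high) match bounds, clipped to [0, 255]."""
        rgb = np.asarray(self.rgb, dtype=float)
        width = self.tolerance * (rgb if self.relative else 255.0)
        return np.clip(rgb - width, 0, 255), np.clip(rgb + width, 0, 255)


@dataclass
class VegetationMask:
    """Boolean per-pixel vegetation layer tied to an image frame.

    ``provenance`` records which stage produced it: ``rfc`` (classifier),
    ``color`` (pseudo-RGB threshold), ``intersection``, ``index-filtered``,
    or ``truth`` for synthetic ground truth.
    """

    mask: np.ndarray
    provenance: str = "rfc"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D frame")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def fraction(self) -> float:
        return float(self.mask.mean())


def color_similarity_mask(
    img: PseudoRGBImage, targets: Sequence[ColorTarget]
) -> VegetationMask:
    """Pixels within tolerance of at least one colour target (union).

    A pixel passes a target when every channel lies inside
    ``target +/- tolerance`` (absolute: tolerance x 255 counts; relative:
    tolerance x target value), bounds clipped to [0, 255].
    """
    if len(targets) == 0:
        raise ValueError("at least one colour target is required")
    rgb = img.data.astype(float)
    passed = np.zeros(rgb.shape[:2], dtype=bool)
    for target in targets:
        lo, hi = target.bounds()
        passed |= np.all((rgb >= lo) & (rgb <= hi), axis=2)
    return VegetationMask(passed, provenance="color")


def intersect_masks(rfc: VegetationMask, color: VegetationMask) -> VegetationMask:
    """Logical AND of classifier and colour masks (the final valid region)."""
    if rfc.shape != color.shape:
        raise ValueError(f"mask shapes differ: {rfc.shape} vs {color.shape}")
    return VegetationMask(rfc.mask & color.mask, provenance="intersection")


def apply_mask_to_cube(cube: ReflectanceCube, mask: VegetationMask) -> ReflectanceCube:
    """Zero out every band of all non-retained pixels; retained spectra pass
    through unchanged."""
    if mask.shape != cube.frame_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match cube frame {cube.frame_shape}"
        )
    data = cube.data.copy()
    data[~mask.mask] = 0.0
    return ReflectanceCube(data, cube.wavelengths, source_id=cube.source_id)


def mask_overlay_report(
    rfc: VegetationMask, color: VegetationMask
) -> tuple[np.ndarray, dict[str, int]]:
    """Four-way agreement partition of the frame.

    Returns a categorical image with codes 0 = neither, 1 = colour-only
    (thresholding noise), 2 = classifier-only, 3 = intersection (retained),
    plus the per-category pixel counts.
    """
    if rfc.shape != color.shape:
        raise ValueError("mask shapes differ")
    codes = (rfc.mask.astype(np.uint8) << 1) | color.mask.astype(np.uint8)
    counts = {
        name: int(np.count_nonzero(codes == code))
        for code, name in enumerate(OVERLAY_CATEGORIES)
    }
    return codes, counts


def save_mask_png(mask: VegetationMask, path) -> Path:
    """Write the mask as an 8-bit PNG (vegetation = 255, background = 0)."""
    path = Path(path)
    Image.fromarray((mask.mask.astype(np.uint8)) * 255, mode="L").save(path)
    return path


def load_mask_png(path, provenance: str = "rfc") -> VegetationMask:
    arr = np.asarray(Image.open(path).convert("L"))
    return VegetationMask(arr > 127, provenance=provenance)
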