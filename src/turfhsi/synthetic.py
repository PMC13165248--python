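"""Synthetic VNIR scenes and breeding populations with known ground truth.

Real imagery for this workflow is not redistributable, so every pipeline
stage is exercised on generated data instead. Scenes are composed from three
parametric endmember spectra — healthy vegetation (green-peaked visible, a
sigmoidal red edge rising to a NIR plateau), soil (bright, monotonically
rising, no red edge) and shadow (flat and dark) — placed as smooth random
blobs to hit a target canopy coverage, with convex vegetation/background
mixtures along blob boundaries emulating the mixed-pixel ambiguity of
limited spatial resolution, plus additive Gaussian sensor noise.

Populations are driven by a latent per-genotype vigor that imperfectly
controls both spectral quality (index means) and growth quantity (vegetation
pixel count), with a configurable quality/quantity coupling, replicate-level
observation noise, and morphological traits (aerial shoot count, runner
count, plant height) correlated with vigor. All generators are pure
functions of their specification and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .cube import ReflectanceCube
from .masks import VegetationMask

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "PopulationEffect",
    "vegetation_spectrum",
    "soil_spectrum",
    "shadow_spectrum",
    "generate_scene",
    "generate_population",
    "EARLY_DATE",
    "LATE_DATE",
]

EARLY_DATE = "6WAT"
LATE_DATE = "16WAT"

#: Index-mean response model for the synthetic population: baseline value and
#: per-unit-quality slope for each vegetation index. Magnitudes follow what
#: healthy vs sparse turf plots typically span.
INDEX_RESPONSE: dict[str, tuple[float, float]] = {
    "NDVI": (0.60, 0.08),
    "EVI": (0.45, 0.08),
    "GNDVI": (0.55, 0.07),
    "RE-NDVI": (0.35, 0.06),
    "mND705": (0.45, 0.07),
    "GCI": (3.5, 0.6),
    "VOG-REI1": (1.5, 0.15),
    "SRI": (6.0, 1.2),
    "PSSRa": (7.0, 1.3),
    "PSSRb": (8.0, 1.4),
    "PSSRc": (3.0, 0.5),
}


@dataclass
class SceneSpec:
    """Parameters of one synthetic VNIR scene."""

    rows: int = 128
    cols: int = 128
    n_bands: int = 204
    coverage: float = 0.3  # target vegetation fraction
    noise_sd: float = 0.01  # additive reflectance noise
    mixed_fraction: float = 0.02  # fraction of the frame turned into boundary mixtures
    shadow_fraction: float = 0.3  # fraction of the background that is shadow
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.coverage + self.mixed_fraction > 1.0:
            raise ValueError("coverage + mixed_fraction must not exceed 1")


@dataclass
class SyntheticScene:
    cube: ReflectanceCube
    truth_mask: VegetationMask
    endmembers: dict[str, np.ndarray]
    spec: SceneSpec


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - center) / width) ** 2))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def vegetation_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Healthy-canopy endmember: green peak near 550 nm, chlorophyll
    absorption trough near 670 nm, red edge at ~700-740 nm, NIR plateau."""
    wl = np.asarray(wavelengths, dtype=float)
    curve = 0.05 + 0.07 * _gauss(wl, 550.0, 40.0) + 0.50 * _sigmoid((wl - 715.0) / 10.0)
    return np.clip(curve, 0.0, 1.0)


def soil_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Bare-soil endmember: brightish, monotonically rising, no red edge."""
    wl = np.asarray(wavelengths, dtype=float)
    return np.clip(0.15 + 0.25 * (wl - wl[0]) / (wl[-1] - wl[0]), 0.0, 1.0)


def shadow_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Shadow endmember: flat and dark across the whole VNIR range."""
    wl = np.asarray(wavelengths, dtype=float)
    return np.clip(0.04 + 0.015 * (wl - wl[0]) / (wl[-1] - wl[0]), 0.0, 1.0)


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Compose a seeded scene with known vegetation truth.

    Vegetation is placed by thresholding a smoothed Gaussian random field at
    the coverage quantile (blob-shaped patches, coverage hit exactly up to
    pixel rounding). A seeded subset of boundary-band pixels becomes convex
    vegetation/background mixtures with weight ~ U(0.3, 0.7); their truth
    label follows the majority component (weight > 0.5).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.rows, spec.cols
    n_pixels = rows * cols
    if spec.coverage > 0 and round(spec.coverage * n_pixels) < 1:
        raise ValueError("coverage unreachable at this frame size")
    wavelengths = np.linspace(400.0, 1000.0, spec.n_bands)
    endmembers = {
        "vegetation": vegetation_spectrum(wavelengths),
        "soil": soil_spectrum(wavelengths),
        "shadow": shadow_spectrum(wavelengths),
    }

    blob_field = ndimage.gaussian_filter(
        rng.standard_normal((rows, cols)), sigma=max(2.0, min(rows, cols) / 12.0)
    )
    if spec.coverage <= 0:
        veg = np.zeros((rows, cols), dtype=bool)
    elif spec.coverage >= 1:
        veg = np.ones((rows, cols), dtype=bool)
    else:
        veg = blob_field > np.quantile(blob_field, 1.0 - spec.coverage)

    shadow_field = ndimage.gaussian_filter(
        rng.standard_normal((rows, cols)), sigma=max(2.0, min(rows, cols) / 20.0)
    )
    background = ~veg
    shadow = np.zeros_like(veg)
    if background.any() and spec.shadow_fraction > 0:
        cut = np.quantile(shadow_field[background], 1.0 - spec.shadow_fraction)
        shadow = background & (shadow_field > cut)

    cube_data = np.empty((rows, cols, spec.n_bands), dtype=np.float64)
    cube_data[veg] = endmembers["vegetation"]
    cube_data[background & ~shadow] = endmembers["soil"]
    cube_data[shadow] = endmembers["shadow"]
    truth = veg.copy()

    n_mixed = int(round(spec.mixed_fraction * n_pixels))
    if n_mixed > 0 and veg.any() and background.any():
        band = ndimage.binary_dilation(veg) ^ ndimage.binary_erosion(veg)
        band_idx = np.flatnonzero(band.ravel())
        if band_idx.size:
            chosen = rng.choice(
                band_idx, size=min(n_mixed, band_idx.size), replace=False
            )
            weights = rng.uniform(0.3, 0.7, size=chosen.size)
            rr, cc = np.unravel_index(chosen, (rows, cols))
            bg_spec = np.where(
                shadow[rr, cc, None], endmembers["shadow"], endmembers["soil"]
            )
            cube_data[rr, cc] = (
                weights[:, None] * endmembers["vegetation"]
                + (1.0 - weights[:, None]) * bg_spec
            )
            truth[rr, cc] = weights > 0.5

    if spec.noise_sd > 0:
        cube_data += rng.normal(0.0, spec.noise_sd, size=cube_data.shape)
    cube_data = np.clip(cube_data, 0.0, 1.0)

    cube = ReflectanceCube(
        cube_data, wavelengths, source_id=f"synthetic-scene-seed{spec.seed}"
    )
    return SyntheticScene(
        cube=cube,
        truth_mask=VegetationMask(truth, provenance="truth"),
        endmembers=endmembers,
        spec=spec,
    )


@dataclass
class PopulationEffect:
    """Effect structure of the synthetic breeding population.

    ``quality_quantity_corr`` is the correlation between the quality and
    quantity latents (both driven by vigor plus independent deviations);
    ``replicate_noise_sd`` scales replicate-level observation noise on each
    index (in units of that index's response slope) and multiplicative noise
    on pixel counts; ``trait_noise_sd`` scales trait noise.
    """

    quality_quantity_corr: float = 0.3
    replicate_noise_sd: float = 0.3
    trait_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.quality_quantity_corr <= 1.0:
            raise ValueError("quality_quantity_corr must lie in (0, 1]")


def generate_population(
    n_genotypes: int,
    replicates: int = 3,
    effect: PopulationEffect = PopulationEffect(),
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-genotype, per-date observations plus trait records.

    Returns
    -------
    observations
        One row per (genotype_id, date_label, replicate): vegetation
        ``pixel_count`` and the eleven index means.
    traits
        One row per genotype: ``aerial_shoot_count``, ``runner_count``,
        ``plant_height``.
    latents
        One row per genotype: ``vigor``, ``quality``, ``quantity`` — the
        ground truth for parameter-recovery checks.
    """
    if n_genotypes < 3:
        raise ValueError("need at least 3 genotypes")
    rng = np.random.default_rng(seed)
    ids = [f"G{i:04d}" for i in range(1, n_genotypes + 1)]
    vigor = rng.standard_normal(n_genotypes)
    c = effect.quality_quantity_corr
    decouple_sd = float(np.sqrt(1.0 / c - 1.0))
    quality = vigor + decouple_sd * rng.standard_normal(n_genotypes)
    quantity = vigor + decouple_sd * rng.standard_normal(n_genotypes)

    late_counts = 6000.0 * np.exp(0.4 * quantity)
    early_factor = rng.uniform(0.5, 0.8, size=n_genotypes)

    rows = []
    for g in range(n_genotypes):
        n_rep = replicates
        if missing_rate > 0 and rng.random() < missing_rate:
            n_rep = int(rng.integers(0, replicates))
        for date, count_base in (
            (EARLY_DATE, late_counts[g] * early_factor[g]),
            (LATE_DATE, late_counts[g]),
        ):
            for rep in range(1, n_rep + 1):
                row = {"genotype_id": ids[g], "date_label": date, "replicate": rep}
                count_noise = (
                    np.exp(rng.normal(0.0, 0.05 * effect.replicate_noise_sd))
                    if effect.replicate_noise_sd > 0
                    else 1.0
                )
                row["pixel_count"] = int(round(count_base * count_noise))
                for name, (base, slope) in INDEX_RESPONSE.items():
                    noise = (
                        rng.normal(0.0, slope * effect.replicate_noise_sd)
                        if effect.replicate_noise_sd > 0
                        else 0.0
                    )
                    seasonal = 0.0 if date == LATE_DATE else -0.3 * slope
                    row[name] = base + slope * quality[g] + seasonal + noise
                rows.append(row)
    observations = pd.DataFrame(rows)

    shoots = np.maximum(
        0, np.round(47.0 + 22.0 * vigor + 6.0 * effect.trait_noise_sd * rng.standard_normal(n_genotypes))
    ).astype(int)
    runners = rng.poisson(np.exp(0.1 + 0.6 * vigor)).astype(int)
    height = 5.2 + 1.6 * rng.standard_normal(n_genotypes)
    traits = pd.DataFrame(
        {
            "genotype_id": ids,
            "aerial_shoot_count": shoots,
            "runner_count": runners,
            "plant_height": np.round(height, 2),
        }
    )
    latents = pd.DataFrame(
        {"genotype_id": ids, "vigor": vigor, "quality": quality, "quantity": quantity}
    )
    return observations, traits, latents
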