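"""End-to-end orchestration: scene processing and population ranking runs.

Two entry points matter to most users. :func:`process_scene` drives one cube
through the imaging stages (hybrid segmentation -> pseudo-RGB colour
refinement -> vegetation-index filtering -> ROI summary) and returns every
intermediate mask for inspection. :func:`run_full` executes a complete
selection run over a population observation table (QC -> per-genotype means
-> rank ledger -> CRS -> stratification -> trait correlations), writing
tabular outputs and a run manifest that makes every reported number
re-derivable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import indices as vi
from .cube import (
    DEFAULT_RGB_BANDS,
    PseudoRGBImage,
    ReflectanceCube,
    RegionOfInterest,
    extract_roi,
    render_pseudo_rgb,
)
from .masks import (
    ColorTarget,
    VegetationMask,
    color_similarity_mask,
    intersect_masks,
    mask_overlay_report,
)
from .ranking import (
    build_rank_ledger,
    correlate_with_traits,
    group_compare,
    qc_filter,
    quality_quantity_ranks,
    stratify,
)
from .segmentation import SegmentationConfig, segment_roi
from .synthetic import LATE_DATE, PopulationEffect, generate_population

__all__ = [
    "PipelineConfig",
    "SceneResult",
    "process_scene",
    "run_full",
    "auto_color_targets",
]


@dataclass
class PipelineConfig:
    """Knobs of the imaging stages, with the workflow defaults."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    rgb_bands: tuple[int, int, int] = DEFAULT_RGB_BANDS
    color_tolerance: float = 0.30
    color_targets: Optional[list[ColorTarget]] = None  # None -> sampled from mask
    #: index filters applied after refinement: name -> (threshold, direction)
    index_filters: dict = field(default_factory=lambda: {"NDVI": (0.2, "ge")})
    computed_indices: tuple[str, ...] = tuple(vi.INDEX_DEFINITIONS)
    normalization: str = "theoretical"


@dataclass
class SceneResult:
    rfc_mask: VegetationMask
    color_mask: VegetationMask
    refined_mask: VegetationMask
    final_mask: VegetationMask
    index_maps: dict
    summary: dict
    overlay_counts: dict
    pseudo_rgb: PseudoRGBImage


def auto_color_targets(
    img: PseudoRGBImage, mask: VegetationMask, tolerance: float = 0.30
) -> list[ColorTarget]:
    """Sample a colour target as the mean RGB of the mask's pixels.

    Stands in for interactively picked healthy-vegetation triplets when the
    pipeline runs unattended; falls back to mid-grey if the mask is empty.
    """
    if mask.pixel_count:
        rgb = tuple(int(round(v)) for v in img.data[mask.mask].mean(axis=0))
    else:
        rgb = (128, 128, 128)
    return [ColorTarget(rgb=rgb, tolerance=tolerance)]


def process_scene(
    cube: ReflectanceCube,
    roi: Optional[RegionOfInterest] = None,
    config: PipelineConfig = PipelineConfig(),
    vegetation_override: Optional[int] = None,
) -> SceneResult:
    """Segment, refine and index-filter one cube (full frame unless an ROI is
    given); returns all intermediate masks plus the ROI summary."""
    if roi is None:
        roi = RegionOfInterest.full_frame(*cube.frame_shape)
    spectra, coords = extract_roi(cube, roi)
    rfc_mask, _, _ = segment_roi(
        cube, spectra, coords, config.segmentation, vegetation_override
    )
    img = render_pseudo_rgb(cube, config.rgb_bands)
    targets = config.color_targets or auto_color_targets(
        img, rfc_mask, config.color_tolerance
    )
    cmask = color_similarity_mask(img, targets)
    refined = intersect_masks(rfc_mask, cmask)
    _, overlay_counts = mask_overlay_report(rfc_mask, cmask)

    index_maps = {
        name: vi.compute_index(cube, name, refined) for name in config.computed_indices
    }
    filter_masks = []
    for name, (threshold, direction) in config.index_filters.items():
        imap = index_maps.get(name) or vi.compute_index(cube, name, refined)
        filter_masks.append(vi.index_threshold_mask(imap, threshold, direction))
    final = vi.combine_index_masks(filter_masks, fallback=refined)
    final = VegetationMask(final.mask & refined.mask, provenance="index-filtered")
    summary = vi.roi_summary(cube, final, index_maps)
    return SceneResult(
        rfc_mask=rfc_mask,
        color_mask=cmask,
        refined_mask=refined,
        final_mask=final,
        index_maps=index_maps,
        summary=summary,
        overlay_counts=overlay_counts,
        pseudo_rgb=img,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def genotype_means(
    observations: pd.DataFrame, date_label: str = LATE_DATE
) -> pd.DataFrame:
    """Per-genotype means of pixel count and index values at one date."""
    sel = observations[observations["date_label"] == date_label]
    if sel.empty:
        raise ValueError(f"no observations at date {date_label!r}")
    value_cols = [
        c for c in sel.columns if c not in ("genotype_id", "date_label", "replicate")
    ]
    return sel.groupby("genotype_id")[value_cols].mean()


def run_full(
    out_dir,
    n_genotypes: int = 20,
    replicates: int = 3,
    seed: int = 0,
    effect: PopulationEffect = PopulationEffect(),
    ranking_date: str = LATE_DATE,
    strata_sizes: tuple[int, int, int] = (20, 10, 20),
    correlation_method: str = "pearson",
    observations: Optional[pd.DataFrame] = None,
    traits: Optional[pd.DataFrame] = None,
) -> dict:
    """Run a complete selection workflow and write its outputs.

    When ``observations``/``traits`` are not supplied, a synthetic population
    is generated under the given effect structure and seed. Strata sizes are
    shrunk proportionally when the population is too small for the default
    (20, 10, 20) split. Returns the run manifest (also written as
    ``manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}

    if observations is None or traits is None:
        observations, traits, latents = generate_population(
            n_genotypes, replicates=replicates, effect=effect, seed=seed
        )
        latents.to_csv(out_dir / "latents.csv", index=False)
    timings["generate"] = time.time() - t0

    retained, exclusions = qc_filter(observations)
    if retained.empty:
        raise RuntimeError("qc: no genotypes with sufficient replicates")
    means = genotype_means(retained, ranking_date)
    ledger = build_rank_ledger(means)
    n = len(ledger)
    n_top, n_mid, n_bottom = strata_sizes
    while n_top + n_mid + n_bottom > n or (n - n_mid) // 2 < n_top:
        n_top, n_mid, n_bottom = max(1, n_top // 2), max(1, n_mid // 2), max(1, n_bottom // 2)
        if (n_top, n_mid, n_bottom) == (1, 1, 1) and n < 3:
            raise RuntimeError("population too small to stratify")
    ledger["stratum"] = stratify(ledger, n_top, n_mid, n_bottom)
    qq = quality_quantity_ranks(ledger)
    timings["rank"] = time.time() - t0 - timings["generate"]

    correlations = correlate_with_traits(ledger, traits, method=correlation_method)
    comparison = group_compare(traits, ledger["stratum"])

    obs_path = out_dir / "observations.csv"
    observations.to_csv(obs_path, index=False)
    traits.to_csv(out_dir / "traits.csv", index=False)
    exclusions.to_csv(out_dir / "qc_exclusions.csv", index=False)
    ledger.to_csv(out_dir / "rank_ledger.csv")
    qq.to_csv(out_dir / "quality_quantity_ranks.csv")
    correlations.to_csv(out_dir / "trait_correlations.csv", index=False)
    comparison.to_csv(out_dir / "group_comparison.csv", index=False)

    manifest = {
        "seed": seed,
        "n_genotypes_input": int(observations["genotype_id"].nunique()),
        "n_genotypes_ranked": n,
        "ranking_date": ranking_date,
        "strata_sizes": [n_top, n_mid, n_bottom],
        "correlation_method": correlation_method,
        "effect": asdict(effect),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": sorted(p.name for p in out_dir.glob("*.csv")),
        "input_hashes": {"observations.csv": _sha256(obs_path)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
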