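"""Hybrid unsupervised/supervised vegetation segmentation.

Pixel spectra from an ROI are min-max scaled per band, embedded into two
dimensions with UMAP, and density-clustered with DBSCAN; points DBSCAN flags
as noise are remapped to the background class. The cluster labels then
bootstrap a Random Forest classifier trained on the scaled spectra (not the
embedding), so the model can classify every pixel of the frame — including
pixels outside any embedded subsample. The vegetation cluster is picked
automatically as the cluster whose mean spectrum maximises NDVI, or supplied
explicitly by the user (the workflow is user-in-the-loop by design).

The whole stage is a pure function of (spectra, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from .cube import ReflectanceCube, band_for_wavelength
from .masks import VegetationMask

__all__ = [
    "SegmentationConfig",
    "EmbeddingResult",
    "ClusterLabeling",
    "ClassifierModel",
    "SegmentationError",
    "scale_spectra",
    "embed_pixels",
    "auto_epsilon",
    "cluster_embedding",
    "train_pixel_classifier",
    "classify_vegetation",
    "pick_vegetation_cluster",
    "segment_roi",
]

BACKGROUND_LABEL = 0


class SegmentationError(RuntimeError):
    """Segmentation could not produce a vegetation cluster."""


@dataclass
class SegmentationConfig:
    """Hyperparameters of the hybrid segmentation stage.

    Defaults are stable, widely used values; epsilon defaults to the automatic
    knee of the k-distance curve when not set interactively.
    """

    n_neighbors: int = 15
    min_dist: float = 0.1
    n_components: int = 2
    seed: int = 42
    min_samples: int = 10
    epsilon: Optional[float] = None  # None -> auto_epsilon
    n_trees: int = 200
    pixel_budget: int = 50_000  # max pixels embedded; larger ROIs are subsampled


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # (n_pixels, 2)
    params: dict


@dataclass
class ClusterLabeling:
    """Per-pixel integer labels: background = 0, clusters 1..K by size."""

    labels: np.ndarray
    epsilon: float
    min_samples: int

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(int(l) for l in np.unique(self.labels) if l != BACKGROUND_LABEL)


@dataclass
class ClassifierModel:
    model: RandomForestClassifier
    classes: tuple[int, ...]
    training_agreement: float
    n_trees: int
    seed: int


def scale_spectra(spectra: np.ndarray) -> np.ndarray:
    """Min-max scale each band to [0, 1]; constant bands map to 0."""
    spectra = np.asarray(spectra, dtype=np.float64)
    if spectra.ndim != 2 or spectra.shape[0] < 1:
        raise ValueError("spectra must be a non-empty (n_pixels, n_bands) table")
    lo = spectra.min(axis=0)
    span = spectra.max(axis=0) - lo
    scaled = np.zeros_like(spectra)
    nz = span > 0
    scaled[:, nz] = (spectra[:, nz] - lo[nz]) / span[nz]
    return scaled


def embed_pixels(
    scaled: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    n_components: int = 2,
    seed: int = 42,
) -> EmbeddingResult:
    """Project scaled spectra to 2-D with UMAP, reproducibly under a seed."""
    import umap  # deferred: numba compilation is slow at import

    scaled = np.asarray(scaled, dtype=np.float64)
    if scaled.shape[0] <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} pixels, got {scaled.shape[0]}"
        )
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        n_components=n_components,
        random_state=seed,
    )
    coords = np.asarray(reducer.fit_transform(scaled), dtype=np.float64)
    return EmbeddingResult(
        coords=coords,
        params={"n_neighbors": n_neighbors, "min_dist": min_dist, "seed": seed},
    )


def auto_epsilon(coords: np.ndarray, min_samples: int = 10) -> float:
    """Default DBSCAN epsilon from the knee of the sorted k-distance curve.

    The distance of every point to its ``min_samples``-th neighbour is sorted
    ascending and the knee is the point of maximum perpendicular distance to
    the chord joining the curve's endpoints — a parameter-free stand-in for
    the interactive per-image epsilon choice.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n < min_samples + 1:
        raise ValueError("need at least min_samples + 1 points")
    nn = NearestNeighbors(n_neighbors=min_samples + 1).fit(coords)
    dists, _ = nn.kneighbors(coords)
    kdist = np.sort(dists[:, -1])
    if kdist[-1] <= 0:  # all points identical
        return float(np.finfo(np.float64).eps * 100)
    x = np.arange(n, dtype=np.float64)
    # perpendicular distance of each curve point to the end-to-end chord
    p0 = np.array([x[0], kdist[0]])
    p1 = np.array([x[-1], kdist[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([x, kdist]) - p0
    perp = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    eps = float(kdist[int(np.argmax(perp))])
    return eps if eps > 0 else float(np.finfo(np.float64).eps * 100)


def cluster_embedding(
    emb: EmbeddingResult, epsilon: float, min_samples: int = 10
) -> ClusterLabeling:
    """DBSCAN on the embedding; noise points are remapped to background (0)
    and clusters renumbered 1..K by decreasing size."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    raw = DBSCAN(eps=epsilon, min_samples=min_samples).fit_predict(emb.coords)
    labels = np.zeros(raw.shape, dtype=np.int64)
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    # stable ordering: by size descending, ties by original DBSCAN id
    order = ids[np.lexsort((ids, -counts))]
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    return ClusterLabeling(labels=labels, epsilon=float(epsilon), min_samples=min_samples)


def train_pixel_classifier(
    scaled: np.ndarray,
    labeling: ClusterLabeling,
    n_trees: int = 200,
    seed: int = 42,
) -> ClassifierModel:
    """Fit a Random Forest on scaled spectra using the cluster labels
    (label bootstrapping)."""
    labels = labeling.labels
    classes = np.unique(labels)
    if classes.size < 2:
        raise SegmentationError(
            "training labels contain a single class; cannot fit a classifier"
        )
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(scaled, labels)
    agreement = float(np.mean(model.predict(scaled) == labels))
    return ClassifierModel(
        model=model,
        classes=tuple(int(c) for c in classes),
        training_agreement=agreement,
        n_trees=n_trees,
        seed=seed,
    )


def classify_vegetation(
    model: ClassifierModel,
    scaled: np.ndarray,
    coords: np.ndarray,
    frame_shape: tuple[int, int],
    vegetation_cluster: int,
) -> VegetationMask:
    """Predict every pixel and mark those assigned to the vegetation cluster.

    ``coords`` maps each spectrum back to its ``(row, col)`` frame position.
    """
    if vegetation_cluster not in model.classes:
        raise ValueError(
            f"label {vegetation_cluster} not among model classes {model.classes}"
        )
    mask = np.zeros(frame_shape, dtype=bool)
    scaled = np.asarray(scaled)
    if scaled.shape[0] == 0:
        return VegetationMask(mask, provenance="rfc")
    pred = model.model.predict(scaled)
    hits = pred == vegetation_cluster
    coords = np.asarray(coords, dtype=int)
    mask[coords[hits, 0], coords[hits, 1]] = True
    return VegetationMask(mask, provenance="rfc")


def _ndvi_of_spectrum(spectrum: np.ndarray, wavelengths: np.ndarray) -> float:
    nir = spectrum[np.argmin(np.abs(wavelengths - 800.0))]
    red = spectrum[np.argmin(np.abs(wavelengths - 670.0))]
    denom = nir + red
    return float((nir - red) / denom) if abs(denom) > 1e-12 else 0.0


def pick_vegetation_cluster(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    labeling: ClusterLabeling,
    override: Optional[int] = None,
    min_fraction: float = 0.05,
) -> int:
    """Choose the vegetation cluster.

    By default the cluster whose mean spectrum maximises NDVI is selected,
    considering only clusters holding at least ``min_fraction`` of the
    clustered pixels — tiny density fragments are unreliable representatives
    and would otherwise hijack the pick on noisy scenes. If no cluster meets
    the size floor, all clusters are considered. A user-supplied ``override``
    label wins unconditionally (user-in-the-loop contract).
    """
    clusters = labeling.cluster_ids
    if override is not None:
        if override not in clusters:
            raise ValueError(f"override label {override} is not a cluster id")
        return int(override)
    if not clusters:
        raise SegmentationError("no non-background clusters found")
    sizes = {cid: int(np.sum(labeling.labels == cid)) for cid in clusters}
    floor = min_fraction * sum(sizes.values())
    candidates = [cid for cid in clusters if sizes[cid] >= floor] or clusters
    best, best_ndvi = candidates[0], -np.inf
    for cid in candidates:
        mean_spec = np.asarray(spectra)[labeling.labels == cid].mean(axis=0)
        ndvi = _ndvi_of_spectrum(mean_spec, wavelengths)
        if ndvi > best_ndvi:
            best, best_ndvi = cid, ndvi
    return int(best)


def segment_roi(
    cube: ReflectanceCube,
    spectra: np.ndarray,
    coords: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
    vegetation_override: Optional[int] = None,
) -> tuple[VegetationMask, ClusterLabeling, ClassifierModel]:
    """Run the full hybrid stage on one ROI's spectra.

    If the ROI exceeds ``config.pixel_budget`` pixels, a seeded random
    subsample is embedded and used for training, after which the classifier
    labels all pixels.
    """
    scaled = scale_spectra(spectra)
    n = scaled.shape[0]
    rng = np.random.default_rng(config.seed)
    if n > config.pixel_budget:
        subset = rng.choice(n, size=config.pixel_budget, replace=False)
        subset.sort()
    else:
        subset = np.arange(n)
    emb = embed_pixels(
        scaled[subset],
        n_neighbors=config.n_neighbors,
        min_dist=config.min_dist,
        n_components=config.n_components,
        seed=config.seed,
    )
    eps = config.epsilon
    if eps is None:
        eps = auto_epsilon(emb.coords, min_samples=config.min_samples)
    labeling = cluster_embedding(emb, epsilon=eps, min_samples=config.min_samples)
    veg = pick_vegetation_cluster(
        spectra[subset], cube.wavelengths, labeling, override=vegetation_override
    )
    model = train_pixel_classifier(
        scaled[subset], labeling, n_trees=config.n_trees, seed=config.seed
    )
    mask = classify_vegetation(model, scaled, coords, cube.frame_shape, veg)
    return mask, labeling, model
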