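"""Independent point-based validation of the final vegetation mask.

Reference points are sampled uniformly without replacement from each image,
manually annotated as vegetation or background, and compared against the
automated mask. Agreement is quantified with overall accuracy, precision,
recall, specificity, F1, and Cohen's kappa (vegetation is the positive class
throughout), both pooled and stratified by canopy-coverage group to expose
the mixed-pixel degradation seen in dense canopies.

The module also provides an exhaustive reconstruction of integer confusion
matrices from a set of printed summary rates — useful for desk-checking a
published validation table (e.g. recovering the kappa implied by rounded
accuracy/precision/recall/specificity at a known N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .masks import VegetationMask

__all__ = [
    "AnnotationPoint",
    "ConfusionReport",
    "sample_points",
    "score_points",
    "confusion_metrics",
    "stratified_metrics",
    "assign_coverage_group",
    "confusion_from_rates",
    "f1_from_precision_recall",
]

VEGETATION = "vegetation"
BACKGROUND = "background"
COVERAGE_GROUPS = ("low", "intermediate", "high")

#: Default vegetation-fraction cutpoints for coverage grouping:
#: f < low_max -> low; f >= high_min -> high; otherwise intermediate.
DEFAULT_COVERAGE_THRESHOLDS = {"low_max": 0.2, "high_min": 0.5}


@dataclass
class AnnotationPoint:
    image_id: str
    row: int
    col: int
    truth: Optional[str] = None  # "vegetation" | "background"
    predicted: Optional[str] = None


@dataclass
class ConfusionReport:
    """Binary confusion counts and the derived agreement metrics.

    ``undefined`` lists metrics whose denominator was zero; these are
    reported as 0.0 with the flag rather than dropped, so reports stay
    complete."""

    tp: int
    fp: int
    fn: int
    tn: int
    group: str = "overall"
    undefined: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def f1(self) -> float:
        return f1_from_precision_recall(self.precision, self.recall)

    @property
    def kappa(self) -> float:
        n = self.n
        if n == 0:
            return 0.0
        p_o = (self.tp + self.tn) / n
        p_e = (
            (self.tp + self.fp) * (self.tp + self.fn)
            + (self.fn + self.tn) * (self.fp + self.tn)
        ) / (n * n)
        if p_e >= 1.0:
            return 0.0
        return (p_o - p_e) / (1.0 - p_e)

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "n": self.n,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "kappa": self.kappa,
            "undefined": list(self.undefined),
        }


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    s = precision + recall
    return 2.0 * precision * recall / s if s > 0 else 0.0


def sample_points(
    image_ids: Sequence[str],
    frame_shape: tuple[int, int],
    n_per_image: int = 200,
    seed: int = 0,
) -> list[AnnotationPoint]:
    """Uniform without-replacement pixel sample per image, seeded."""
    rows, cols = frame_shape
    n_pixels = rows * cols
    if n_per_image > n_pixels:
        raise ValueError(
            f"cannot sample {n_per_image} points from {n_pixels} pixels"
        )
    rng = np.random.default_rng(seed)
    points: list[AnnotationPoint] = []
    for image_id in image_ids:
        flat = rng.choice(n_pixels, size=n_per_image, replace=False)
        for f in flat:
            points.append(AnnotationPoint(str(image_id), int(f // cols), int(f % cols)))
    return points


def score_points(
    points: Sequence[AnnotationPoint], masks: Mapping[str, VegetationMask]
) -> list[AnnotationPoint]:
    """Fill each point's prediction from its image's mask value."""
    scored = []
    for p in points:
        if p.image_id not in masks:
            raise KeyError(f"no mask supplied for image {p.image_id!r}")
        value = masks[p.image_id].mask[p.row, p.col]
        scored.append(
            AnnotationPoint(p.image_id, p.row, p.col, p.truth, VEGETATION if value else BACKGROUND)
        )
    return scored


def confusion_metrics(
    points: Sequence[AnnotationPoint], group: str = "overall"
) -> ConfusionReport:
    """Confusion counts + metrics over annotated, scored points."""
    if len(points) == 0:
        raise ValueError("need at least one annotated point")
    tp = fp = fn = tn = 0
    for p in points:
        if p.truth is None or p.predicted is None:
            raise ValueError("all points must carry truth and prediction")
        if p.predicted == VEGETATION:
            tp += p.truth == VEGETATION
            fp += p.truth == BACKGROUND
        else:
            fn += p.truth == VEGETATION
            tn += p.truth == BACKGROUND
    undefined = []
    if tp + fp == 0:
        undefined.append("precision")
    if tp + fn == 0:
        undefined.append("recall")
    if tn + fp == 0:
        undefined.append("specificity")
    return ConfusionReport(tp, fp, fn, tn, group=group, undefined=tuple(undefined))


def stratified_metrics(
    points: Sequence[AnnotationPoint], coverage_labels: Mapping[str, str]
) -> dict[str, ConfusionReport]:
    """Per-coverage-group reports plus the pooled overall report."""
    by_group: dict[str, list[AnnotationPoint]] = {}
    for p in points:
        if p.image_id not in coverage_labels:
            raise KeyError(f"image {p.image_id!r} has no coverage label")
        by_group.setdefault(coverage_labels[p.image_id], []).append(p)
    reports = {
        g: confusion_metrics(pts, group=g) for g, pts in sorted(by_group.items())
    }
    reports["overall"] = confusion_metrics(points, group="overall")
    return reports


def assign_coverage_group(
    mask: VegetationMask,
    thresholds: Mapping[str, float] = DEFAULT_COVERAGE_THRESHOLDS,
) -> str:
    """Canopy-coverage stratum from the mask's vegetation fraction."""
    low_max, high_min = thresholds["low_max"], thresholds["high_min"]
    if not (0 < low_max < high_min < 1):
        raise ValueError("need 0 < low_max < high_min < 1")
    f = mask.fraction()
    if f < low_max:
        return "low"
    if f >= high_min:
        return "high"
    return "intermediate"


def confusion_from_rates(
    n: int,
    accuracy: float,
    precision: float,
    recall: float,
    specificity: float,
    decimals: int = 4,
) -> list[ConfusionReport]:
    """All integer confusion matrices at total count ``n`` whose four rates
    round to the given values.

    Exhaustive over TP, with the recall and precision constraints bounding
    FN and FP to narrow integer windows; accuracy and specificity are then
    checked directly. Useful for recovering unreported quantities (e.g.
    kappa) implied by a published table of rounded rates.
    """
    h = 0.5 * 10.0 ** (-decimals)
    found: list[ConfusionReport] = []

    def rounds_to(value: float, target: float) -> bool:
        return abs(round(value, decimals) - round(target, decimals)) < h

    for tp in range(0, n + 1):
        # positives P = TP + FN constrained by recall = TP / P
        if recall <= 0:
            p_lo, p_hi = tp, n
        else:
            p_lo = int(np.ceil(tp / min(recall + h, 1.0)))
            p_hi = int(np.floor(tp / max(recall - h, 1e-12)))
        for p_total in range(max(p_lo, tp), min(p_hi, n) + 1):
            fn = p_total - tp
            # predicted positives PP = TP + FP constrained by precision
            if precision <= 0:
                pp_lo, pp_hi = tp, n - fn
            else:
                pp_lo = int(np.ceil(tp / min(precision + h, 1.0)))
                pp_hi = int(np.floor(tp / max(precision - h, 1e-12)))
            for pp in range(max(pp_lo, tp), min(pp_hi, n - fn) + 1):
                fp = pp - tp
                tn = n - tp - fn - fp
                if tn < 0:
                    continue
                rep = ConfusionReport(tp, fp, fn, tn)
                if (
                    rounds_to(rep.accuracy, accuracy)
                    and rounds_to(rep.precision, precision)
                    and rounds_to(rep.recall, recall)
                    and rounds_to(rep.specificity, specificity)
                ):
                    found.append(rep)
    return found
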