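"""Genotype ranking and selection: QC, rank aggregation, the Combined
Ranking Score (CRS), stratified selection, and trait correlations.

The CRS merges two aspects of turfgrass performance with equal weight:
physiological *quality*, represented by the per-genotype ranks of five
vegetation indices (PSSRb, NDVI, GCI, RE-NDVI, VOG-REI1), and growth
*quantity*, represented by the rank of vegetation pixel count ("area"):

    CRS = (sum of five index ranks + 5.0 x area rank) / 10

Rank 1 is best in every column (highest index mean; largest pixel count), so
a lower CRS means a better genotype. The area rank is weighted 5x so the
single quantity column balances the five quality columns 50:50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indices import FIVE_QUALITY_INDICES

__all__ = [
    "FIVE_QUALITY_INDICES",
    "AREA_RANK_WEIGHT",
    "qc_filter",
    "rank_column",
    "build_rank_ledger",
    "combined_ranking_score",
    "stratify",
    "quality_quantity_ranks",
    "correlate_with_traits",
    "group_compare",
]

#: Weight applied to the area (pixel-count) rank so quantity balances the
#: five quality indices 50:50.
AREA_RANK_WEIGHT = 5.0
MIN_REPLICATES = 3

STRATA = ("Superior", "Intermediate", "Inferior")


def qc_filter(
    observations: pd.DataFrame, min_replicates: int = MIN_REPLICATES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genotypes with insufficient replicates at any acquisition date.

    ``observations`` holds one row per (genotype_id, date_label, replicate).
    Genotypes with fewer than ``min_replicates`` rows at any date present in
    the table are excluded (image-acquisition failures make their means
    unreliable).

    Returns the retained observations and an exclusion report with columns
    ``genotype_id``, ``date_label``, ``n_replicates``, ``reason``.
    """
    counts = (
        observations.groupby(["genotype_id", "date_label"], sort=True)
        .size()
        .rename("n_replicates")
        .reset_index()
    )
    dates = observations["date_label"].unique()
    full = pd.MultiIndex.from_product(
        [observations["genotype_id"].unique(), dates],
        names=["genotype_id", "date_label"],
    )
    counts = (
        counts.set_index(["genotype_id", "date_label"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    bad = counts[counts["n_replicates"] < min_replicates].copy()
    bad["reason"] = bad["n_replicates"].map(
        lambda n: f"only {n} replicate(s) (< {min_replicates})"
    )
    excluded_ids = set(bad["genotype_id"])
    retained = observations[~observations["genotype_id"].isin(excluded_ids)].copy()
    return retained, bad.reset_index(drop=True)


def rank_column(
    values: Sequence[float] | pd.Series, direction: str = "higher_is_better"
) -> np.ndarray:
    """Rank a per-genotype column with average ranks for ties; rank 1 = best.

    Missing values (NaN) are ranked strictly last, sharing an average rank
    among themselves.
    """
    if direction not in ("higher_is_better", "lower_is_better"):
        raise ValueError(f"unknown direction {direction!r}")
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("ranking needs at least 2 genotypes")
    key = -vals if direction == "higher_is_better" else vals
    missing = np.isnan(vals)
    key = key.copy()
    key[missing] = np.inf  # NaNs sort last regardless of direction
    return stats.rankdata(key, method="average")


def build_rank_ledger(
    genotype_means: pd.DataFrame,
    quality_indices: Sequence[str] = FIVE_QUALITY_INDICES,
    area_column: str = "pixel_count",
) -> pd.DataFrame:
    """Construct the per-genotype rank ledger and CRS.

    ``genotype_means`` has one row per genotype (index or ``genotype_id``
    column) with the five quality-index mean columns and the vegetation
    pixel-count column. Returns a ledger with per-index ranks
    (``rank_<index>``), ``rank_area``, ``crs``, and ``crs_rank`` (position in
    the final ascending-CRS ordering, ties broken by area rank then id).
    """
    df = genotype_means.copy()
    if "genotype_id" in df.columns:
        df = df.set_index("genotype_id")
    missing = [c for c in (*quality_indices, area_column) if c not in df.columns]
    if missing:
        raise KeyError(f"genotype table lacks columns {missing}")
    ledger = pd.DataFrame(index=df.index)
    for name in quality_indices:
        ledger[f"rank_{name}"] = rank_column(df[name], "higher_is_better")
    ledger["rank_area"] = rank_column(df[area_column], "higher_is_better")
    ledger["crs"] = combined_ranking_score(ledger, quality_indices)
    # final ordering: CRS ascending, ties by area rank then genotype id
    ledger = ledger.loc[
        ledger.assign(_id=ledger.index.astype(str))
        .sort_values(["crs", "rank_area", "_id"], kind="mergesort")
        .index
    ]
    ledger["crs_rank"] = np.arange(1, len(ledger) + 1)
    return ledger


def combined_ranking_score(
    ledger: pd.DataFrame,
    quality_indices: Sequence[str] = FIVE_QUALITY_INDICES,
    area_weight: float = AREA_RANK_WEIGHT,
) -> pd.Series:
    """CRS = (sum of the five index ranks + area rank x weight) / 10."""
    cols = [f"rank_{name}" for name in quality_indices]
    missing = [c for c in (*cols, "rank_area") if c not in ledger.columns]
    if missing:
        raise KeyError(f"rank ledger lacks columns {missing}")
    block = ledger[cols + ["rank_area"]]
    if block.isna().any().any():
        raise ValueError("rank ledger contains missing ranks")
    divisor = len(quality_indices) + area_weight
    return (ledger[cols].sum(axis=1) + ledger["rank_area"] * area_weight) / divisor


def stratify(
    ledger: pd.DataFrame, n_top: int = 20, n_mid: int = 10, n_bottom: int = 20
) -> pd.Series:
    """Label the selection strata on a CRS-ranked ledger.

    The top ``n_top`` CRS ranks become ``Superior``, the bottom ``n_bottom``
    ``Inferior``, and ``n_mid`` ranks centred on the median rank (starting on
    the lower side for even splits) become ``Intermediate``; everything else
    is ``none``.
    """
    n = len(ledger)
    if n_top + n_mid + n_bottom > n:
        raise ValueError("strata sizes exceed population size")
    ranks = ledger["crs_rank"].to_numpy()
    mid_start = (n - n_mid) // 2 + 1  # lower-start rule on even splits
    mid_end = mid_start + n_mid - 1
    if mid_start <= n_top or mid_end > n - n_bottom:
        raise ValueError("strata overlap; population too small for requested sizes")
    labels = np.full(n, "none", dtype=object)
    labels[ranks <= n_top] = "Superior"
    labels[(ranks >= mid_start) & (ranks <= mid_end)] = "Intermediate"
    labels[ranks > n - n_bottom] = "Inferior"
    return pd.Series(labels, index=ledger.index, name="stratum")


def quality_quantity_ranks(
    ledger: pd.DataFrame, quality_indices: Sequence[str] = FIVE_QUALITY_INDICES
) -> pd.DataFrame:
    """Quality rank (mean of the five per-index ranks, re-ranked) vs quantity
    rank (pixel-count rank) — the two half-scores whose low mutual correlation
    motivates combining them."""
    cols = [f"rank_{name}" for name in quality_indices]
    mean_quality = ledger[cols].mean(axis=1)
    out = pd.DataFrame(index=ledger.index)
    out["quality_rank"] = rank_column(mean_quality, "lower_is_better")
    out["quantity_rank"] = ledger["rank_area"]
    return out


def correlate_with_traits(
    ledger: pd.DataFrame,
    traits: pd.DataFrame,
    trait_columns: Sequence[str] = ("aerial_shoot_count", "runner_count", "plant_height"),
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate CRS against manually measured traits.

    Pairing is by genotype id; unmatched genotypes are dropped. Returns a
    table with columns ``trait``, ``coefficient``, ``p_value``, ``n``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    tr = traits.copy()
    if "genotype_id" in tr.columns:
        tr = tr.set_index("genotype_id")
    shared = ledger.index.intersection(tr.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 paired genotypes")
    crs = ledger.loc[shared, "crs"].to_numpy(dtype=float)
    rows = []
    for trait in trait_columns:
        y = tr.loc[shared, trait].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if np.nanstd(y[ok]) == 0 or np.std(crs[ok]) == 0:
            raise ValueError(f"constant column; correlation undefined for {trait!r}")
        if method == "pearson":
            r, p = stats.pearsonr(crs[ok], y[ok])
        else:
            r, p = stats.spearmanr(crs[ok], y[ok])
        rows.append(
            {"trait": trait, "coefficient": float(r), "p_value": float(p), "n": int(ok.sum())}
        )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_compare(
    traits: pd.DataFrame,
    strata: pd.Series,
    trait_columns: Sequence[str] = ("aerial_shoot_count", "runner_count", "plant_height"),
) -> pd.DataFrame:
    """Welch two-sample comparison of Superior vs Inferior strata per trait.

    Returns per-trait group means +/- SD for Superior, Inferior, and the total
    population, the Welch t-test p-value, and significance stars at
    0.05 / 0.01 / 0.001.
    """
    tr = traits.copy()
    if "genotype_id" in tr.columns:
        tr = tr.set_index("genotype_id")
    sup_ids = strata.index[strata == "Superior"]
    inf_ids = strata.index[strata == "Inferior"]
    rows = []
    for trait in trait_columns:
        a = tr.loc[tr.index.intersection(sup_ids), trait].dropna().to_numpy(dtype=float)
        b = tr.loc[tr.index.intersection(inf_ids), trait].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"group too small for trait {trait!r}")
        total = tr[trait].dropna().to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "trait": trait,
                "superior_mean": float(a.mean()),
                "superior_sd": float(a.std(ddof=1)),
                "inferior_mean": float(b.mean()),
                "inferior_sd": float(b.std(ddof=1)),
                "total_mean": float(total.mean()),
                "total_sd": float(total.std(ddof=1)),
                "t_statistic": float(t),
                "p_value": float(p),
                "significance": _stars(float(p)),
            }
        )
    return pd.DataFrame(rows)
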