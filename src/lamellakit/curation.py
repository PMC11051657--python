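"""Particle stratification and selection.

Implements the selection schemes used to probe how lamella thickness and
particle depth affect subtomogram averaging: equal-count thickness groups,
fixed-size depth bins at regular centers, the high-quality filter
(thin lamella AND outside the ion-damage zone), nested random subsets with
a thickness-distribution bias check, and whole-tomogram random selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionSpec",
    "split_equal_count",
    "select_depth_bins",
    "select_high_quality",
    "random_subsets",
    "select_by_tomogram",
]


@dataclass(frozen=True)
class SelectionSpec:
    """Parameters of one curation run; the seed is recorded in all outputs."""

    seed: int
    thickness_bounds_nm: tuple[float, float] | None = None
    depth_min_nm: float | None = None
    depth_centers_nm: tuple[float, ...] | None = None
    per_center_n: int = 1000
    subset_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.thickness_bounds_nm is not None:
            lo, hi = self.thickness_bounds_nm
            if not lo < hi:
                raise ValueError("thickness bounds must be ordered (low, high)")
        if self.per_center_n <= 0:
            raise ValueError("per_center_n must be positive")
        if any(s <= 0 for s in self.subset_sizes):
            raise ValueError("subset sizes must be positive")


def split_equal_count(
    table: pd.DataFrame, key: str, k: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split particles into k groups of (near-)equal size by sorted key.

    Groups are contiguous blocks in ascending ``key`` order (stable sort, so
    ties keep input order); when the count is not divisible by k the extra
    particles go to the lowest-key groups, so sizes differ by at most one.
    Returns the table with a ``group`` column (0 = lowest key) and a report
    of per-group size and key range.
    """
    if table.empty:
        raise ValueError("cannot split an empty table")
    if key not in table.columns:
        raise KeyError(f"key column {key!r} not present")
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(table)
    if k > n:
        raise ValueError(f"k={k} exceeds particle count {n}")
    order = np.argsort(table[key].to_numpy(), kind="stable")
    base, extra = divmod(n, k)
    sizes = [base + (1 if g < extra else 0) for g in range(k)]
    labels = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes):
        labels[order[start : start + size]] = g
        start += size
    out = table.copy()
    out["group"] = labels
    key_vals = table[key].to_numpy()
    report = pd.DataFrame(
        {
            "group": range(k),
            "size": sizes,
            "key_min": [key_vals[labels == g].min() for g in range(k)],
            "key_max": [key_vals[labels == g].max() for g in range(k)],
        }
    )
    return out, report


def select_depth_bins(
    table: pd.DataFrame,
    centers: list[float],
    per_center_n: int,
    depth_key: str = "depth_nm",
) -> tuple[dict[float, pd.DataFrame], pd.DataFrame]:
    """For each depth center, pick the n particles closest to it in depth.

    Groups may overlap across neighbouring centers when few particles lie
    near the surface (as happens for the shallowest bins).  Returns the
    per-center groups and a report with group sizes, the realized depth
    range, and the overlap fraction with the previous center's group.
    """
    if depth_key not in table.columns:
        raise KeyError(f"depth column {depth_key!r} not present")
    if per_center_n > len(table):
        raise ValueError(
            f"per_center_n={per_center_n} exceeds available particles ({len(table)})"
        )
    depth = table[depth_key].to_numpy(dtype=float)
    groups: dict[float, pd.DataFrame] = {}
    rows = []
    prev_idx: set | None = None
    for c in centers:
        order = np.argsort(np.abs(depth - c), kind="stable")[:per_center_n]
        sel = table.iloc[np.sort(order)]
        groups[c] = sel
        idx = set(table.index[order])
        overlap = (
            len(idx & prev_idx) / per_center_n if prev_idx is not None else 0.0
        )
        rows.append(
            {
                "center_nm": c,
                "n": len(sel),
                "depth_min": sel[depth_key].min(),
                "depth_max": sel[depth_key].max(),
                "overlap_with_previous": overlap,
            }
        )
        prev_idx = idx
    return groups, pd.DataFrame(rows)


def select_high_quality(
    table: pd.DataFrame,
    thickness_max_nm: float = 180.0,
    depth_min_nm: float = 30.0,
    thickness_key: str = "local_thickness_nm",
    depth_key: str = "depth_nm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """High-quality filter: thin lamella AND outside the damage zone.

    Keeps particles whose tomogram's local thickness is strictly below
    ``thickness_max_nm`` and whose depth is strictly above ``depth_min_nm``
    (particles closer to a surface than the damage-layer depth are
    excluded).  Returns the filtered table and a per-tomogram breakdown.
    """
    for col in (thickness_key, depth_key):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not present")
    keep = (table[thickness_key] < thickness_max_nm) & (table[depth_key] > depth_min_nm)
    kept = table[keep]
    breakdown = (
        pd.DataFrame(
            {
                "tomogram_id": table["tomogram_id"],
                "kept": keep.astype(int),
            }
        )
        .groupby("tomogram_id", sort=False)
        .agg(n_total=("kept", "size"), n_kept=("kept", "sum"))
        .reset_index()
    )
    return kept, breakdown


def random_subsets(
    table: pd.DataFrame,
    sizes: list[int],
    seed: int,
    match_key: str | None = "local_thickness_nm",
    p_threshold: float = 0.01,
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Nested random subsets of ascending sizes (sequential reduction).

    A single random permutation defines all subsets: subset of size s is the
    first s entries, so each smaller subset is contained in every larger
    one.  If ``match_key`` is given, each subset's distribution of that key
    is compared against the full table with a two-sample Kolmogorov-Smirnov
    test; p-values below ``p_threshold`` trigger a warning (biased draw).
    """
    if sorted(sizes) != list(sizes):
        raise ValueError("sizes must be ascending")
    if sizes and sizes[-1] > len(table):
        raise ValueError(f"largest size {sizes[-1]} exceeds table size {len(table)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    subsets: dict[int, pd.DataFrame] = {}
    rows = []
    for s in sizes:
        sel = table.iloc[np.sort(perm[:s])]
        subsets[s] = sel
        p = np.nan
        if match_key is not None and match_key in table.columns:
            p = stats.ks_2samp(
                sel[match_key].to_numpy(), table[match_key].to_numpy()
            ).pvalue
            if p < p_threshold:
                logger.warning(
                    "subset of %d: %s distribution differs from full table "
                    "(KS p=%.3g < %.3g)",
                    s,
                    match_key,
                    p,
                    p_threshold,
                )
        rows.append({"size": s, "ks_pvalue": p, "seed": seed})
    return subsets, pd.DataFrame(rows)


def select_by_tomogram(
    table: pd.DataFrame, n_target: int, seed: int
) -> pd.DataFrame:
    """Randomly select whole tomograms until n_target particles are reached.

    Tomograms are added in random order until the cumulative particle count
    first reaches the target; the last tomogram is then randomly trimmed so
    the selection has exactly ``n_target`` particles.  Selecting tomograms
    rather than particles keeps per-tomogram particle counts high, which
    maximizes the benefit of multi-particle refinement.
    """
    if n_target > len(table):
        raise ValueError(f"n_target={n_target} exceeds table size {len(table)}")
    rng = np.random.default_rng(seed)
    tomos = table["tomogram_id"].unique()
    order = rng.permutation(len(tomos))
    chosen: list[pd.DataFrame] = []
    total = 0
    for i in order:
        sub = table[table["tomogram_id"] == tomos[i]]
        if total + len(sub) >= n_target:
            need = n_target - total
            trim = np.sort(rng.choice(len(sub), size=need, replace=False))
            chosen.append(sub.iloc[trim])
            total += need
            break
        chosen.append(sub)
        total += len(sub)
    return pd.concat(chosen)
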