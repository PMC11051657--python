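"""Lamella geometry: plane fitting, in-silico straightening, surface finding.

FIB-milled lamellae sit tilted in the tomogram frame (pretilt, loading
offset, non-flatness), so particle Z coordinates from template matching do
not directly encode distance to the lamella surface.  The straightening
procedure fits a reference plane through the raw template-match coordinates
of one tomogram, subtracts it from each particle's Z ("flattening", which
centers the slab around z = 0), locates the two lamella surfaces as the
sharp drop-offs of the flattened-Z histogram, and derives per-particle
depth (distance to the closest surface) and the tomogram's local thickness.

All paper-facing quantities (depth, thickness) are in nm; STAR coordinates
are voxels and are converted through the per-tomogram pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateGeometryError",
    "InsufficientSupportError",
    "DegenerateHistogramError",
    "LamellaFrame",
    "fit_reference_plane",
    "flatten_z",
    "estimate_surfaces",
    "particle_depth",
    "local_thickness",
    "wedge_profile",
    "straighten_tomogram",
    "straighten_particles",
]


class DegenerateGeometryError(ValueError):
    """Plane fit impossible: fewer than 3 points or collinear (x, y)."""


class InsufficientSupportError(ValueError):
    """Too few particles to estimate lamella surfaces."""


class DegenerateHistogramError(ValueError):
    """Flattened-Z histogram has no bin meeting the plateau criterion."""


@dataclass(frozen=True)
class LamellaFrame:
    """Fitted lamella geometry of one tomogram.

    ``plane`` holds (a, b, c) of z_plane(x, y) = a*x + b*y + c in voxel
    units; surface offsets are in the flattened frame, in nm.
    """

    tomogram_id: str
    plane: tuple[float, float, float]
    z_bottom_nm: float
    z_top_nm: float
    bin_width_nm: float
    n_support: int
    pixel_size_a: float

    def __post_init__(self) -> None:
        if not self.z_top_nm > self.z_bottom_nm:
            raise ValueError(
                f"{self.tomogram_id}: top surface ({self.z_top_nm}) must lie "
                f"above bottom surface ({self.z_bottom_nm})"
            )
        if self.n_support < 3:
            raise ValueError(f"{self.tomogram_id}: n_support < 3")

    @property
    def thickness_nm(self) -> float:
        return self.z_top_nm - self.z_bottom_nm


def fit_reference_plane(
    coords: np.ndarray, robust: bool = False, tomogram_id: str = "?"
) -> tuple[float, float, float]:
    """Least-squares plane z = a*x + b*y + c through (x, y, z) points.

    With ``robust=True`` an iteratively reweighted (Huber) fit is used
    instead of ordinary least squares; the default matches fitting through
    the raw template matches without outlier rejection.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("coords must be an (n, 3) array of (x, y, z)")
    if pts.shape[0] < 3:
        raise DegenerateGeometryError(
            f"tomogram {tomogram_id}: need >=3 points to fit a plane, got {pts.shape[0]}"
        )
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    if np.linalg.matrix_rank(A) < 3:
        raise DegenerateGeometryError(
            f"tomogram {tomogram_id}: (x, y) support is collinear; plane fit is rank-deficient"
        )
    z = pts[:, 2]
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    if robust:
        coef = _irls_huber(A, z, coef)
    return (float(coef[0]), float(coef[1]), float(coef[2]))


def _irls_huber(A: np.ndarray, z: np.ndarray, coef: np.ndarray, n_iter: int = 20) -> np.ndarray:
    for _ in range(n_iter):
        r = z - A @ coef
        s = 1.4826 * np.median(np.abs(r - np.median(r))) or 1.0
        k = 1.345 * s
        w = np.where(np.abs(r) <= k, 1.0, k / np.maximum(np.abs(r), 1e-300))
        W = np.sqrt(w)[:, None]
        new, *_ = np.linalg.lstsq(A * W, z * np.sqrt(w), rcond=None)
        if np.allclose(new, coef, rtol=0, atol=1e-12):
            coef = new
            break
        coef = new
    return coef


def flatten_z(
    table: pd.DataFrame, plane: tuple[float, float, float]
) -> pd.DataFrame:
    """Subtract the fitted plane from each particle's Z coordinate.

    Adds a ``z_flat`` column (voxels); the slab ends up roughly centered
    around z_flat = 0.
    """
    a, b, c = plane
    if not np.all(np.isfinite([a, b, c])):
        raise ValueError("plane coefficients must be finite")
    out = table.copy()
    out["z_flat"] = out["z"] - (a * out["x"] + b * out["y"] + c)
    return out


def estimate_surfaces(
    z_flat: np.ndarray,
    pixel_size_a: float,
    bin_width_nm: float = 5.0,
    dropoff_fraction: float = 0.5,
    min_support: int = 100,
    tomogram_id: str = "?",
) -> tuple[float, float]:
    """Locate the lamella surfaces from the flattened-Z histogram.

    The particle count per flattened-Z bin is roughly constant inside the
    slab and drops off sharply at the surfaces.  The plateau level is the
    median count over occupied interior bins; scanning outward from the
    central bin, the bottom/top edge is the outer edge of the outermost
    contiguous bin whose count still reaches ``dropoff_fraction`` of the
    plateau.  Returns (z_bottom_nm, z_top_nm) in the flattened frame.
    """
    z = np.asarray(z_flat, dtype=float)
    if z.size < min_support:
        raise InsufficientSupportError(
            f"tomogram {tomogram_id}: {z.size} particles < min_support={min_support}"
        )
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be positive")
    if not 0 < dropoff_fraction < 1:
        raise ValueError("dropoff_fraction must lie in (0, 1)")
    z_nm = z * pixel_size_a / 10.0
    lo = np.floor(z_nm.min() / bin_width_nm) - 1
    hi = np.ceil(z_nm.max() / bin_width_nm) + 1
    edges = bin_width_nm * np.arange(lo, hi + 1)
    counts, _ = np.histogram(z_nm, bins=edges)

    occupied = np.nonzero(counts > 0)[0]
    interior = occupied[1:-1] if occupied.size > 2 else occupied
    plateau = float(np.median(counts[interior]))
    threshold = dropoff_fraction * plateau

    center = int(np.searchsorted(edges, np.median(z_nm), side="right") - 1)
    center = min(max(center, 0), len(counts) - 1)
    if counts[center] < threshold:
        raise DegenerateHistogramError(
            f"tomogram {tomogram_id}: central bin below {dropoff_fraction} x plateau"
        )
    i = center
    while i - 1 >= 0 and counts[i - 1] >= threshold:
        i -= 1
    j = center
    while j + 1 < len(counts) and counts[j + 1] >= threshold:
        j += 1
    return float(edges[i]), float(edges[j + 1])


def particle_depth(
    z_flat_nm: np.ndarray, z_bottom_nm: float, z_top_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Distance (nm) from each particle to the closest lamella surface.

    No distinction is made between top and bottom surface.  Particles
    outside the slab get a negative depth and ``in_slab=False`` — they are
    retained so that surface-estimation errors stay inspectable.
    """
    if not z_bottom_nm < z_top_nm:
        raise ValueError("z_bottom_nm must be below z_top_nm")
    z = np.asarray(z_flat_nm, dtype=float)
    depth = np.minimum(z - z_bottom_nm, z_top_nm - z)
    return depth, depth >= 0


def local_thickness(frame: LamellaFrame) -> float:
    """Local lamella thickness (nm) of one tomogram."""
    return frame.thickness_nm


def wedge_profile(
    frames: list[LamellaFrame], positions: list[float] | None = None
) -> pd.DataFrame:
    """Thickness along the lamella, front to back.

    ``positions`` are front-to-back coordinates or sortable labels, one per
    frame; defaults to the frame order.  Milling geometry makes thickness
    increase from front to back (wedge shape).
    """
    if positions is None:
        positions = list(range(len(frames)))
    if len(positions) != len(frames):
        raise ValueError("positions and frames must have equal length")
    df = pd.DataFrame(
        {
            "position": positions,
            "tomogram_id": [f.tomogram_id for f in frames],
            "thickness_nm": [f.thickness_nm for f in frames],
        }
    )
    return df.sort_values("position", kind="stable").reset_index(drop=True)


def straighten_tomogram(
    table: pd.DataFrame,
    pixel_size_a: float,
    tomogram_id: str,
    bin_width_nm: float = 5.0,
    dropoff_fraction: float = 0.5,
    min_support: int = 100,
    robust: bool = False,
) -> tuple[pd.DataFrame, LamellaFrame]:
    """Full straightening of one tomogram's particles.

    Fits the reference plane, flattens Z, estimates surfaces, and attaches
    ``z_flat``, ``depth_nm``, ``in_slab`` and ``local_thickness_nm``
    columns.  Returns the augmented table and the fitted
    :class:`LamellaFrame`.
    """
    coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    plane = fit_reference_plane(coords, robust=robust, tomogram_id=tomogram_id)
    flat = flatten_z(table, plane)
    zb, zt = estimate_surfaces(
        flat["z_flat"].to_numpy(),
        pixel_size_a,
        bin_width_nm=bin_width_nm,
        dropoff_fraction=dropoff_fraction,
        min_support=min_support,
        tomogram_id=tomogram_id,
    )
    frame = LamellaFrame(
        tomogram_id=tomogram_id,
        plane=plane,
        z_bottom_nm=zb,
        z_top_nm=zt,
        bin_width_nm=bin_width_nm,
        n_support=len(table),
        pixel_size_a=pixel_size_a,
    )
    z_flat_nm = flat["z_flat"].to_numpy() * pixel_size_a / 10.0
    depth, in_slab = particle_depth(z_flat_nm, zb, zt)
    flat["depth_nm"] = depth
    flat["in_slab"] = in_slab
    flat["local_thickness_nm"] = frame.thickness_nm
    return flat, frame


def straighten_particles(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    bin_width_nm: float = 5.0,
    dropoff_fraction: float = 0.5,
    min_support: int = 100,
    robust: bool = False,
) -> tuple[pd.DataFrame, list[LamellaFrame]]:
    """Straighten every tomogram of a multi-tomogram particle table.

    ``metadata`` maps tomogram_id to pixel_size_a (Å/voxel).  Tomograms are
    processed independently; returns the concatenated augmented table (in
    original row order) and one LamellaFrame per tomogram.
    """
    pixel = metadata.set_index("tomogram_id")["pixel_size_a"]
    frames: list[LamellaFrame] = []
    parts: list[pd.DataFrame] = []
    for tomo, sub in table.groupby("tomogram_id", sort=False):
        if tomo not in pixel.index:
            raise KeyError(f"tomogram {tomo} missing from metadata")
        flat, frame = straighten_tomogram(
            sub,
            float(pixel.loc[tomo]),
            str(tomo),
            bin_width_nm=bin_width_nm,
            dropoff_fraction=dropoff_fraction,
            min_support=min_support,
            robust=robust,
        )
        frames.append(frame)
        parts.append(flat)
    out = pd.concat(parts).loc[table.index]
    return out, frames
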