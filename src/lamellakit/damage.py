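"""Ion-damage quantification from normalized cross-correlation scores.

Template-matching CC scores act as a per-particle quality proxy: near the
lamella surface, gallium implantation and collision cascades degrade
structure and depress CC; deeper than the damage layer the scores level
off to a constant plateau.  Scores are first normalized per tomogram
(CC/CC_max), then the depth of the damage layer is estimated by fitting a
hinge (ramp-plateau) model

    cc(d) = c_surface + (c_plateau - c_surface) * min(d, d_break) / d_break

with the breakpoint scanned on a grid and the linear parameters solved in
closed form at each grid point; a bootstrap gives a confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DamageFit",
    "normalize_cc",
    "estimate_damage_depth",
    "fit_linear_trend",
]


@dataclass(frozen=True)
class DamageFit:
    """Hinge-model fit of normalized CC versus depth."""

    d_break_nm: float
    c_plateau: float
    c_surface: float
    ci_low_nm: float
    ci_high_nm: float
    residual_rms: float
    n: int
    damage_detected: bool


def normalize_cc(table: pd.DataFrame, cc_key: str = "cc_score") -> pd.DataFrame:
    """Add ``cc_norm`` = CC / max(CC) within each tomogram.

    The per-tomogram maximum is exactly 1 after normalization, which makes
    scores comparable across tomograms with different contrast.
    """
    if cc_key not in table.columns:
        raise KeyError(f"column {cc_key!r} not present")
    out = table.copy()
    maxima = out.groupby("tomogram_id")[cc_key].transform("max")
    bad = maxima <= 0
    if bad.any():
        culprit = out.loc[bad, "tomogram_id"].iloc[0]
        raise ValueError(f"tomogram {culprit}: non-positive maximum CC score")
    out["cc_norm"] = out[cc_key] / maxima
    return out


def _hinge_sse(depth: np.ndarray, cc: np.ndarray, grid: np.ndarray):
    """Closed-form least squares of cc on the hinge basis at every grid point.

    For fixed d_break the model is linear in (c_surface, delta) with
    regressor r = min(d, d_break)/d_break; simple-regression formulas give
    the SSE for all grid points vectorized.
    """
    n = depth.size
    r = np.minimum(depth[None, :], grid[:, None]) / grid[:, None]  # (g, n)
    r_mean = r.mean(axis=1)
    cc_mean = cc.mean()
    r_c = r - r_mean[:, None]
    cc_c = cc - cc_mean
    sxx = np.einsum("gn,gn->g", r_c, r_c)
    sxy = r_c @ cc_c
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / np.maximum(sxx, 1e-300), 0.0)
    intercept = cc_mean - slope * r_mean
    syy = float(cc_c @ cc_c)
    # rounding can push a perfect fit's SSE slightly negative
    sse = np.maximum(syy - slope * sxy, 0.0)
    return sse, slope, intercept


def estimate_damage_depth(
    depth_nm: np.ndarray,
    cc_norm: np.ndarray,
    grid_nm: tuple[float, float, float] = (5.0, 80.0, 1.0),
    n_bootstrap: int = 200,
    seed: int = 0,
    f_threshold: float = 10.0,
    min_particles: int = 50,
) -> DamageFit:
    """Estimate the damage-layer depth by hinge regression.

    The breakpoint is scanned over ``grid_nm`` = (start, stop, step); at
    each candidate the two linear parameters are solved by least squares
    and the SSE-minimizing triple is returned, with a seeded bootstrap
    percentile CI (2.5/97.5%) over ``n_bootstrap`` case resamples.

    If the hinge does not reduce the SSE over a constant fit by an F-like
    criterion (``f_threshold`` on the F statistic with 2 and n-3 degrees of
    freedom), the profile is considered flat: ``damage_detected`` is False
    and the breakpoint is reported at the grid minimum.
    """
    d = np.asarray(depth_nm, dtype=float)
    cc = np.asarray(cc_norm, dtype=float)
    if d.size != cc.size:
        raise ValueError("depth and cc arrays must have equal length")
    if d.size < min_particles:
        raise ValueError(f"need >= {min_particles} particles, got {d.size}")
    start, stop, step = grid_nm
    grid = np.arange(start, stop + step / 2, step)

    sse, slope, intercept = _hinge_sse(d, cc, grid)
    best = int(np.argmin(sse))
    sse_best = float(sse[best])
    c_surface = float(intercept[best])
    c_plateau = float(intercept[best] + slope[best])
    d_break = float(grid[best])
    n = d.size
    rms = float(np.sqrt(sse_best / n))

    sse_const = float(np.sum((cc - cc.mean()) ** 2))
    # hinge adds 2 parameters (slope and breakpoint) over the constant model
    if sse_best <= 1e-12 * max(sse_const, 1.0):
        f_stat = np.inf if sse_const > sse_best else 0.0
    else:
        f_stat = ((sse_const - sse_best) / 2.0) / (sse_best / max(n - 3, 1))
    detected = f_stat >= f_threshold
    if not detected:
        d_break = float(grid[0])

    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        sse_b, _, _ = _hinge_sse(d[idx], cc[idx], grid)
        boots[i] = grid[int(np.argmin(sse_b))]
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])

    return DamageFit(
        d_break_nm=d_break,
        c_plateau=c_plateau,
        c_surface=c_surface,
        ci_low_nm=float(ci_low),
        ci_high_nm=float(ci_high),
        residual_rms=rms,
        n=n,
        damage_detected=bool(detected),
    )


def fit_linear_trend(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least-squares line through (x, y); returns (slope, intercept, r).

    Used e.g. for the linear dependence of CTF-fit resolution on local
    lamella thickness.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct x values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)
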