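"""Fourier shell correlation and Rosenthal-Henderson B-factor fitting.

FSC measures the agreement of two independently refined half-maps per
spatial-frequency shell; resolution is read where the curve first crosses a
threshold (0.143 by default, 0.5 optional).  The Rosenthal-Henderson
analysis relates particle number N to resolution d through

    1/d^2 = (2/B) * ln N + const,

so the slope of 1/d^2 against ln N yields an overall B-factor (A^2)
describing how quickly resolution improves as particles are added.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FscCurve",
    "ResolutionEstimate",
    "NoValidFitError",
    "compute_fsc",
    "resolution_at",
    "rosenthal_henderson_fit",
]


class NoValidFitError(ValueError):
    """Rosenthal-Henderson fit impossible (degenerate N or non-positive slope)."""


@dataclass(frozen=True)
class FscCurve:
    """Per-shell correlation between two half-maps.

    ``shell_freq`` is the shell-center spatial frequency in 1/A, strictly
    ascending, bounded by Nyquist = 1/(2 * pixel_size).
    """

    shell_freq: np.ndarray
    fsc: np.ndarray
    box_size: int
    pixel_size: float

    def __post_init__(self) -> None:
        f = np.asarray(self.shell_freq, float)
        if f.size == 0:
            raise ValueError("empty FSC curve")
        if not np.all(np.diff(f) > 0):
            raise ValueError("shell_freq must be strictly ascending")
        nyquist = 1.0 / (2.0 * self.pixel_size)
        if f[-1] > nyquist * (1 + 1e-9):
            raise ValueError("shell_freq exceeds Nyquist")
        if not np.all(np.isfinite(self.fsc)):
            raise ValueError("fsc values must be finite")

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_invA": self.shell_freq, "fsc": self.fsc})


class ResolutionEstimate(NamedTuple):
    resolution_a: float
    crossed: bool  # False means the curve never dropped below the threshold


def _shell_index(box: int) -> np.ndarray:
    """Integer shell index per Fourier voxel (shells one voxel wide)."""
    k = np.fft.fftfreq(box) * box
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    return np.rint(r).astype(int)


def compute_fsc(
    map_a: np.ndarray,
    map_b: np.ndarray,
    pixel_size: float,
    mask: np.ndarray | None = None,
) -> FscCurve:
    """Fourier shell correlation between two cubic volumes.

    Per shell s: FSC(s) = Re sum(Fa * conj(Fb)) / sqrt(sum|Fa|^2 sum|Fb|^2),
    with shells one Fourier voxel wide, after voxelwise masking.  No mask
    correction (phase randomization) is applied.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"half-map shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 3 or len(set(a.shape)) != 1:
        raise ValueError("maps must be cubic 3D volumes")
    if mask is not None:
        mask = np.asarray(mask, dtype=float)
        if mask.shape != a.shape:
            raise ValueError("mask shape mismatch")
        if mask.min() < 0 or mask.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")
        a = a * mask
        b = b * mask
    box = a.shape[0]
    Fa = np.fft.fftn(a)
    Fb = np.fft.fftn(b)
    shell = _shell_index(box).ravel()
    n_shells = box // 2 + 1
    valid = shell < n_shells

    cross = np.real(Fa.ravel() * np.conj(Fb.ravel()))
    pa = np.abs(Fa.ravel()) ** 2
    pb = np.abs(Fb.ravel()) ** 2
    num = np.bincount(shell[valid], weights=cross[valid], minlength=n_shells)
    da = np.bincount(shell[valid], weights=pa[valid], minlength=n_shells)
    db = np.bincount(shell[valid], weights=pb[valid], minlength=n_shells)

    # shell 0 is the DC term; report shells 1..box//2
    s = np.arange(1, n_shells)
    denom = np.sqrt(da[1:] * db[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = np.where(denom > 0, num[1:] / denom, 0.0)
    freq = s / (box * pixel_size)
    return FscCurve(shell_freq=freq, fsc=fsc, box_size=box, pixel_size=pixel_size)


def resolution_at(curve: FscCurve, threshold: float = 0.143) -> ResolutionEstimate:
    """Resolution (A) where the FSC first drops below ``threshold``.

    The crossing frequency is interpolated linearly between the bracketing
    shells.  If the curve never crosses, the Nyquist resolution is returned
    with ``crossed=False``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    f = curve.shell_freq
    y = curve.fsc
    below = np.nonzero(y < threshold)[0]
    if below.size == 0:
        return ResolutionEstimate(1.0 / curve.nyquist, False)
    i = below[0]
    if i == 0:
        return ResolutionEstimate(1.0 / f[0], True)
    f_cross = f[i - 1] + (y[i - 1] - threshold) / (y[i - 1] - y[i]) * (f[i] - f[i - 1])
    return ResolutionEstimate(1.0 / f_cross, True)


def rosenthal_henderson_fit(
    points: Sequence[tuple[float, float]],
    fit_range: Sequence[int] | None = None,
    nyquist_a: float | None = None,
) -> tuple[float, float]:
    """Fit 1/d^2 = (2/B) ln N + intercept; returns (B in A^2, intercept).

    ``points`` are (N, d) pairs with d in A.  ``fit_range`` selects point
    indices for the linear regime; by default all points are used except
    those at the Nyquist ceiling (within one shell of ``nyquist_a`` when
    given), since resolution saturates there and no longer follows the
    model.  A non-positive slope (resolution not improving with N) raises
    :class:`NoValidFitError` — such series have no linear regime to fit.
    """
    pts = [(float(n), float(d)) for n, d in points]
    if fit_range is None:
        idx = list(range(len(pts)))
        if nyquist_a is not None:
            # exclude points saturated at the ceiling (within ~one shell)
            idx = [i for i in idx if pts[i][1] > nyquist_a * 1.05]
    else:
        idx = list(fit_range)
    sel = [pts[i] for i in idx]
    ns = {n for n, _ in sel}
    if len(sel) < 2 or len(ns) < 2:
        raise NoValidFitError(
            "need at least two points with distinct N in the fit range"
        )
    x = np.log([n for n, _ in sel])
    y = np.array([1.0 / d**2 for _, d in sel])
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise NoValidFitError(
            f"non-positive slope ({slope:.3g}): no linear regime to fit a B-factor"
        )
    return 2.0 / float(slope), float(intercept)
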