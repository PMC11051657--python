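"""Dose-symmetric tilt schemes, cumulative dose and exposure weighting.

A dose-symmetric acquisition alternates tilt angles around a starting
angle (the lamella pretilt) so the low tilts, which carry the most
high-resolution signal, receive the least accumulated electron dose.
Frequency-dependent exposure weights follow the critical-exposure model
of Grant & Grigorieff (2015): the critical exposure at spatial frequency
k (1/A) is Ne(k) = a*k^b + c with published constants a=0.245, b=-1.665,
c=2.81, and signal after dose D is attenuated by exp(-D / (2*Ne)).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TiltScheme",
    "dose_symmetric_scheme",
    "cumulative_dose",
    "exposure_weight",
    "CRITICAL_EXPOSURE_A",
    "CRITICAL_EXPOSURE_B",
    "CRITICAL_EXPOSURE_C",
]

# critical-exposure constants (Grant & Grigorieff 2015), overridable per call
CRITICAL_EXPOSURE_A = 0.245
CRITICAL_EXPOSURE_B = -1.665
CRITICAL_EXPOSURE_C = 2.81


@dataclass(frozen=True)
class TiltScheme:
    """Ordered tilt angles as acquired, with optional per-tilt dose."""

    angles_deg: tuple[float, ...]
    pretilt_deg: float
    step_deg: float
    group: int
    span_deg: float
    dose_per_tilt: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.angles_deg)) != len(self.angles_deg):
            raise ValueError("tilt angles must be unique")
        if any(
            abs(a - self.pretilt_deg) > self.span_deg + 1e-9 for a in self.angles_deg
        ):
            raise ValueError("angle outside pretilt +/- span")

    def __len__(self) -> int:
        return len(self.angles_deg)

    @property
    def cumulative_dose(self) -> np.ndarray:
        """Dose accumulated before each exposure, in acquisition order."""
        if self.dose_per_tilt is None:
            raise ValueError("dose_per_tilt not set")
        return cumulative_dose(self, self.dose_per_tilt)

    def write_rawtlt(self, path: str | Path) -> None:
        """Write angles, one per line, in acquisition order (rawtlt-style)."""
        Path(path).write_text(
            "".join(f"{a:.2f}\n" for a in self.angles_deg)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"tilt_deg": self.angles_deg})
        if self.dose_per_tilt is not None:
            df["dose_before_e_per_a2"] = self.cumulative_dose
        return df


def dose_symmetric_scheme(
    pretilt_deg: float,
    step_deg: float,
    group: int,
    span_deg: float,
    dose_per_tilt: float | None = None,
    positive_first: bool = True,
) -> TiltScheme:
    """Build a dose-symmetric tilt scheme about a pretilt.

    Acquisition starts at the pretilt, then alternates sides in blocks of
    ``group`` consecutive steps (positive branch first by default) until
    pretilt +/- span is covered.  The angle set is always
    {pretilt + k*step : k = -span/step .. +span/step}; ``group`` changes
    only the acquisition order.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    if group < 1:
        raise ValueError("group must be >= 1")
    n_steps = span_deg / step_deg
    if span_deg <= 0 or abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("span_deg must be a positive multiple of step_deg")
    m = int(round(n_steps))
    pos = [pretilt_deg + k * step_deg for k in range(1, m + 1)]
    neg = [pretilt_deg - k * step_deg for k in range(1, m + 1)]
    first, second = (pos, neg) if positive_first else (neg, pos)
    angles = [pretilt_deg]
    i = j = 0
    turn_first = True
    while i < m or j < m:
        if turn_first and i < m:
            take = min(group, m - i)
            angles.extend(first[i : i + take])
            i += take
        elif not turn_first and j < m:
            take = min(group, m - j)
            angles.extend(second[j : j + take])
            j += take
        turn_first = not turn_first
    return TiltScheme(
        angles_deg=tuple(angles),
        pretilt_deg=pretilt_deg,
        step_deg=step_deg,
        group=group,
        span_deg=span_deg,
        dose_per_tilt=dose_per_tilt,
    )


def cumulative_dose(scheme: TiltScheme, dose_per_tilt: float) -> np.ndarray:
    """Dose (e-/A^2) accumulated before each tilt, in acquisition order.

    The i-th exposure (1-based) sees (i-1)*dose_per_tilt; the total applied
    dose is n * dose_per_tilt.
    """
    if dose_per_tilt <= 0:
        raise ValueError("dose_per_tilt must be positive")
    return dose_per_tilt * np.arange(len(scheme), dtype=float)


def exposure_weight(
    freq_invA: np.ndarray | float,
    accumulated_dose: np.ndarray | float,
    a: float = CRITICAL_EXPOSURE_A,
    b: float = CRITICAL_EXPOSURE_B,
    c: float = CRITICAL_EXPOSURE_C,
) -> np.ndarray | float:
    """Exposure (dose) weight exp(-dose / (2*Ne(freq))) in (0, 1].

    ``Ne(freq) = a*freq^b + c`` is the critical exposure; frequencies in
    1/A, dose in e-/A^2.  Weights compose multiplicatively over doses.
    """
    freq = np.asarray(freq_invA, dtype=float)
    dose = np.asarray(accumulated_dose, dtype=float)
    if np.any(freq <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    ne = a * freq**b + c
    w = np.exp(-dose / (2.0 * ne))
    if np.isscalar(freq_invA) and np.isscalar(accumulated_dose):
        return float(w)
    return w
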