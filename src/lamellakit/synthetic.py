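"""Synthetic data generation for every analysis stage.

Three generators stand in for the study's tomograms so the full pipeline
is testable without external data:

* tilted wedge-shaped lamella slabs with particles distributed uniformly
  inside, exported as voxel coordinates with known ground truth (plane,
  per-particle depth, local thickness);
* per-particle CC scores depressed within a damage layer near the
  surfaces and constant deeper, under either a ramp-plateau (hinge) or an
  exponential-recovery model, so the breakpoint estimator is exercised
  both under its own model and under misspecification;
* half-map pairs whose per-shell spectral SNR follows scale*N*exp(-B*k^2/2),
  giving an expected FSC of SNR/(1+SNR) per shell, so FSC-derived
  resolution improves with particle number N the way a Rosenthal-Henderson
  model predicts.

The half-map generator works purely in the Fourier-shell SNR domain: no
projection physics, no CTF, no missing wedge.  That is sufficient to
exercise the FSC and B-factor machinery, but results on it say nothing
about alignment or reconstruction artifacts in real maps.

All outputs are reproducible given (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DamageModel",
    "LamellaScenario",
    "load_scenario",
    "simulate_lamella_particles",
    "simulate_cc_scores",
    "simulate_halfmaps",
]


@dataclass(frozen=True)
class DamageModel:
    """CC-versus-depth model for score simulation.

    ``ramp``: cc rises linearly from c_surface at depth 0 to c_plateau at
    d_break_nm and is constant beyond.  ``exponential``: cc approaches the
    plateau as c_plateau*(1 - kappa*exp(-d/lambda_nm)) with
    kappa = 1 - c_surface/c_plateau.
    """

    kind: str = "ramp"
    d_break_nm: float = 30.0
    lambda_nm: float = 12.0
    c_surface: float = 0.6
    c_plateau: float = 0.95
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("ramp", "exponential"):
            raise ValueError("kind must be 'ramp' or 'exponential'")
        if not 0 < self.c_surface <= self.c_plateau <= 1:
            raise ValueError("require 0 < c_surface <= c_plateau <= 1")

    def mean_cc(self, depth_nm: np.ndarray) -> np.ndarray:
        d = np.asarray(depth_nm, dtype=float)
        if self.kind == "ramp":
            frac = np.minimum(d, self.d_break_nm) / self.d_break_nm
            return self.c_surface + (self.c_plateau - self.c_surface) * frac
        kappa = 1.0 - self.c_surface / self.c_plateau
        return self.c_plateau * (1.0 - kappa * np.exp(-d / self.lambda_nm))


@dataclass(frozen=True)
class LamellaScenario:
    """Ground-truth description of a simulated multi-tomogram lamella.

    Defaults echo the study conditions: local thickness spanning roughly
    43-255 nm front to back across the tomogram series, ~5 degree lamella
    tilt relative to the tomogram frame, reconstruction pixel size 4.9 A,
    and a ramp damage model with a 30-nm break.
    """

    seed: int
    n_tomograms: int = 12
    thickness_front_nm: float = 43.0
    wedge_slope: float = 0.0106  # nm thickness per nm of front-back position
    lamella_length_nm: float = 20000.0
    plane_a: float = 0.09  # ~5 degree tilt of the slab in the tomogram frame
    plane_b: float = -0.04
    plane_c: float = 250.0  # voxel offset of the slab midplane
    particles_per_tomogram: float = 1700.0
    tomogram_extent_nm: tuple[float, float] = (900.0, 900.0)
    pixel_size_a: float = 4.9
    damage: DamageModel = field(default_factory=DamageModel)

    def __post_init__(self) -> None:
        t_back = self.thickness_front_nm + self.wedge_slope * self.lamella_length_nm
        if self.thickness_front_nm <= 0 or t_back <= 0:
            raise ValueError("thickness must be positive over the whole extent")
        if self.particles_per_tomogram <= 0:
            raise ValueError("particle density must be positive")

    def thickness_at(self, position_nm: np.ndarray) -> np.ndarray:
        """Local thickness (nm) at a front-to-back position (nm)."""
        return self.thickness_front_nm + self.wedge_slope * np.asarray(
            position_nm, dtype=float
        )


def load_scenario(path: str | Path) -> LamellaScenario:
    """Load a scenario from a YAML config file."""
    cfg = yaml.safe_load(Path(path).read_text())
    damage = DamageModel(**cfg.pop("damage", {}))
    for key in ("tomogram_extent_nm",):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return LamellaScenario(damage=damage, **cfg)


def simulate_lamella_particles(
    scenario: LamellaScenario,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate template-match coordinates inside a tilted wedge-shaped slab.

    Tomograms are placed front to back along the lamella; within each, the
    slab is {(x, y, z): |z - plane(x, y)| <= t(x)/2} with t(x) growing
    linearly along the front-back axis.  Per-tomogram particle counts are
    Poisson around the configured density.  Returns (particles, truth):
    particles carries voxel coordinates, random Euler angles, CC scores
    drawn from the damage model, and the tomogram id; truth carries the
    true plane, per-particle depth and local thickness.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    nm_per_vox = scenario.pixel_size_a / 10.0
    ext_x, ext_y = scenario.tomogram_extent_nm
    positions = np.linspace(
        0.0, scenario.lamella_length_nm, scenario.n_tomograms
    )
    part_rows = []
    truth_rows = []
    for t_idx, pos in enumerate(positions):
        tomo = f"tomo_{t_idx + 1:03d}"
        n = int(rng.poisson(scenario.particles_per_tomogram))
        if n == 0:
            continue
        x_nm = rng.uniform(0, ext_x, n)
        y_nm = rng.uniform(0, ext_y, n)
        t_local = scenario.thickness_at(pos + x_nm)
        dz_nm = rng.uniform(-0.5, 0.5, n) * t_local
        x_vox = x_nm / nm_per_vox
        y_vox = y_nm / nm_per_vox
        z_mid = (
            scenario.plane_a * x_vox + scenario.plane_b * y_vox + scenario.plane_c
        )
        z_vox = z_mid + dz_nm / nm_per_vox
        depth = t_local / 2.0 - np.abs(dz_nm)
        part_rows.append(
            pd.DataFrame(
                {
                    "tomogram_id": tomo,
                    "x": x_vox,
                    "y": y_vox,
                    "z": z_vox,
                    "rot": rng.uniform(-180, 180, n),
                    "tilt": np.degrees(np.arccos(rng.uniform(-1, 1, n))),
                    "psi": rng.uniform(-180, 180, n),
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "tomogram_id": tomo,
                    "position_nm": pos,
                    "plane_a": scenario.plane_a,
                    "plane_b": scenario.plane_b,
                    "plane_c": scenario.plane_c,
                    "true_depth_nm": depth,
                    "true_thickness_nm": t_local,
                }
            )
        )
    if not part_rows:
        raise ValueError("scenario produced zero particles")
    particles = pd.concat(part_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    particles["cc_score"] = simulate_cc_scores(
        truth["true_depth_nm"].to_numpy(), scenario.damage, rng
    )
    return particles, truth


def simulate_cc_scores(
    depth_nm: np.ndarray,
    model: DamageModel,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw CC scores from the damage model at the given depths.

    Gaussian noise of sd ``model.noise_sd`` is added and redrawn where the
    result would be non-positive (truncation keeps cc > 0).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    mean = np.asarray(
        DamageModel.mean_cc(model, np.maximum(depth_nm, 0.0)), dtype=float
    )
    cc = mean + rng.normal(0.0, model.noise_sd, size=mean.shape)
    for _ in range(100):
        bad = cc <= 0
        if not bad.any():
            break
        cc[bad] = mean[bad] + rng.normal(0.0, model.noise_sd, size=int(bad.sum()))
    return np.maximum(cc, 1e-6)


def simulate_halfmaps(
    box: int,
    pixel_size: float,
    n_particles: float,
    b_factor: float,
    scale: float = 1e-4,
    seed: int | np.random.Generator = 0,
    structure: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Half-map pair with per-shell SNR(k) = scale * N * exp(-B * k^2 / 2).

    A band-limited random "structure" is drawn once (or passed in, so a
    series over N shares it); each half-map adds independent unit white
    noise to the structure scaled per shell so the spectral SNR follows
    the Rosenthal-Henderson form.  Returns (map_a, map_b, table) with the
    table holding shell frequency, the target SNR and the expected FSC
    SNR/(1+SNR).
    """
    if box < 32 or box % 2:
        raise ValueError("box must be even and >= 32")
    rng = (
        np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    )
    k = np.fft.fftfreq(box, d=pixel_size)
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    kmag = np.sqrt(kx**2 + ky**2 + kz**2)
    shell = np.rint(kmag * box * pixel_size).astype(int)
    nyq_shell = box // 2

    snr = scale * n_particles * np.exp(-b_factor * kmag**2 / 2.0)
    snr[shell > nyq_shell] = 0.0  # band limit at Nyquist

    if structure is None:
        structure = rng.standard_normal((box, box, box))
    S = np.fft.fftn(structure)
    amp = np.sqrt(snr)
    a = np.fft.ifftn(S * amp).real + rng.standard_normal((box, box, box))
    b = np.fft.ifftn(S * amp).real + rng.standard_normal((box, box, box))

    s_idx = np.arange(1, nyq_shell + 1)
    freq = s_idx / (box * pixel_size)
    snr_shell = np.array(
        [snr[shell == s].mean() if np.any(shell == s) else 0.0 for s in s_idx]
    )
    expected = pd.DataFrame(
        {
            "freq_invA": freq,
            "snr": snr_shell,
            "expected_fsc": snr_shell / (1.0 + snr_shell),
        }
    )
    return a, b, expected
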