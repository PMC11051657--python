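"""End-to-end analyses: thickness stratification, depth/damage, quality.

Each runner consumes either a real particle STAR file (with per-tomogram
metadata) or a synthetic scenario, executes the corresponding analysis
with the library modules, and writes STAR/CSV reports whose headers carry
the seed and a config hash, so seeded reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import curation, damage, geometry, io, resolution, synthetic

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_thickness_analysis",
    "run_depth_analysis",
    "run_quality_comparison",
    "run_demo",
]

DEPTH_CENTERS_NM = tuple(float(c) for c in range(5, 55, 5))
SUBSET_SIZES = (250, 500, 1000, 2000, 4000, 8000, 16114)
DEPTH_THICKNESS_WINDOW_NM = (140.0, 190.0)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of (``star_path`` + ``metadata_path``, ``scenario``) must be
    active; the seed is recorded in every output header.
    """

    out_dir: Path
    seed: int
    star_path: Path | None = None
    metadata_path: Path | None = None
    scenario: synthetic.LamellaScenario | None = None
    n_thickness_groups: int = 3
    depth_centers_nm: tuple[float, ...] = DEPTH_CENTERS_NM
    per_center_n: int = 1000
    subset_sizes: tuple[int, ...] = SUBSET_SIZES
    thickness_max_nm: float = 180.0
    depth_min_nm: float = 30.0
    bin_width_nm: float = 5.0
    dropoff_fraction: float = 0.5
    damage_grid_nm: tuple[float, float, float] = (5.0, 80.0, 1.0)
    n_bootstrap: int = 200

    def __post_init__(self) -> None:
        real = self.star_path is not None
        if real == (self.scenario is not None):
            raise ValueError(
                "exactly one of (star_path, scenario) must be provided"
            )
        self.out_dir = Path(self.out_dir)

    def config_hash(self) -> str:
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("out_dir", "star_path", "metadata_path")
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_particles(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return a straightened particle table with depth/thickness columns."""
    if cfg.scenario is not None:
        particles, _truth = synthetic.simulate_lamella_particles(cfg.scenario)
        meta = pd.DataFrame(
            {
                "tomogram_id": particles["tomogram_id"].unique(),
                "pixel_size_a": cfg.scenario.pixel_size_a,
            }
        )
    else:
        particles = io.read_particles(cfg.star_path)
        if cfg.metadata_path is None:
            raise ValueError("real STAR input needs tomogram metadata")
        meta = io.read_tomogram_metadata(cfg.metadata_path)
    table, frames = geometry.straighten_particles(
        particles,
        meta,
        bin_width_nm=cfg.bin_width_nm,
        dropoff_fraction=cfg.dropoff_fraction,
    )
    # manual thickness from metadata overrides the geometry-derived value
    if "thickness_nm" in meta.columns:
        manual = meta.set_index("tomogram_id")["thickness_nm"]
        override = table["tomogram_id"].map(manual)
        table.loc[override.notna(), "local_thickness_nm"] = override[override.notna()]
    frames_df = pd.DataFrame(
        {
            "tomogram_id": [f.tomogram_id for f in frames],
            "plane_a": [f.plane[0] for f in frames],
            "plane_b": [f.plane[1] for f in frames],
            "plane_c": [f.plane[2] for f in frames],
            "z_bottom_nm": [f.z_bottom_nm for f in frames],
            "z_top_nm": [f.z_top_nm for f in frames],
            "thickness_nm": [f.thickness_nm for f in frames],
            "n_support": [f.n_support for f in frames],
        }
    )
    return table, frames_df


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={cfg.seed} config={cfg.config_hash()}\n")
        df.to_csv(fh, index=False)


def run_thickness_analysis(cfg: PipelineConfig) -> dict:
    """Stratify particles into equal-count thickness groups with subsets.

    Emits one STAR file per thickness group, nested random subsets per
    group, and a manifest; when half-maps are simulated (synthetic runs) a
    Rosenthal-Henderson table per group is added.
    """
    table, frames_df = _load_particles(cfg)
    if "local_thickness_nm" not in table.columns:
        raise ValueError(
            "no local thickness available: provide metadata thickness_nm or "
            "run on coordinates that allow surface estimation"
        )
    out = cfg.out_dir / "thickness"
    out.mkdir(parents=True, exist_ok=True)
    labeled, report = curation.split_equal_count(
        table, "local_thickness_nm", cfg.n_thickness_groups
    )
    manifest_rows = []
    for g in range(cfg.n_thickness_groups):
        sub = labeled[labeled["group"] == g].drop(columns="group")
        io.write_particles(sub, out / f"thickness_group_{g}.star")
        sizes = [s for s in cfg.subset_sizes if s <= len(sub)]
        subsets, ks_report = curation.random_subsets(
            sub, sizes, seed=cfg.seed + g, match_key="local_thickness_nm"
        )
        for s, subset in subsets.items():
            io.write_particles(subset, out / f"thickness_group_{g}_n{s}.star")
        manifest_rows.append(
            {
                "group": g,
                "size": len(sub),
                "thickness_min_nm": report.loc[g, "key_min"],
                "thickness_max_nm": report.loc[g, "key_max"],
                "subsets": ",".join(str(s) for s in sizes),
                "seed": cfg.seed + g,
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    _write_csv(manifest, out / "manifest.csv", cfg)
    _write_csv(frames_df, out / "frames.csv", cfg)

    rh_table = None
    if cfg.scenario is not None:
        rh_table = _simulated_rh_series(cfg)
        _write_csv(rh_table, out / "rosenthal_henderson.csv", cfg)
    return {"manifest": manifest, "frames": frames_df, "rh": rh_table}


def _simulated_rh_series(
    cfg: PipelineConfig,
    box: int = 48,
    b_factor: float = 500.0,
    scale: float = 4e-3,
    pixel: float = 3.0,
) -> pd.DataFrame:
    """Resolution versus particle count from simulated half-map pairs."""
    rng = np.random.default_rng(cfg.seed)
    structure = rng.standard_normal((box, box, box))
    rows = []
    for n in (250, 500, 1000, 2000, 4000, 8000, 16000):
        a, b, _ = synthetic.simulate_halfmaps(
            box, pixel, n, b_factor, scale=scale, seed=rng, structure=structure
        )
        curve = resolution.compute_fsc(a, b, pixel)
        est = resolution.resolution_at(curve, 0.143)
        rows.append(
            {"n_particles": n, "resolution_a": est.resolution_a, "at_nyquist": not est.crossed}
        )
    df = pd.DataFrame(rows)
    usable = df[~df["at_nyquist"]]
    if len(usable) >= 2:
        b_fit, _ = resolution.rosenthal_henderson_fit(
            list(zip(usable["n_particles"], usable["resolution_a"]))
        )
        df["b_factor_fit"] = b_fit
    return df


def run_depth_analysis(cfg: PipelineConfig) -> dict:
    """Depth-resolved particle groups and the damage-layer estimate.

    Restricts to the thickness window used for the damage analysis,
    selects fixed-size groups around 5-nm depth centers, normalizes CC per
    tomogram, and estimates the damage-layer depth by hinge regression.
    """
    table, _ = _load_particles(cfg)
    lo, hi = DEPTH_THICKNESS_WINDOW_NM
    windowed = table[
        (table["local_thickness_nm"] >= lo) & (table["local_thickness_nm"] <= hi)
    ]
    if windowed.empty:
        raise ValueError(
            f"no tomograms with local thickness in [{lo}, {hi}] nm; "
            "cannot run the depth analysis"
        )
    out = cfg.out_dir / "depth"
    out.mkdir(parents=True, exist_ok=True)
    per_center = min(cfg.per_center_n, len(windowed))
    groups, overlap = curation.select_depth_bins(
        windowed, list(cfg.depth_centers_nm), per_center
    )
    for c, g in groups.items():
        io.write_particles(g, out / f"depth_{c:g}nm.star")
    _write_csv(overlap, out / "depth_groups.csv", cfg)

    normed = damage.normalize_cc(windowed)
    in_slab = normed[normed["depth_nm"] > 0]
    fit = damage.estimate_damage_depth(
        in_slab["depth_nm"].to_numpy(),
        in_slab["cc_norm"].to_numpy(),
        grid_nm=cfg.damage_grid_nm,
        n_bootstrap=cfg.n_bootstrap,
        seed=cfg.seed,
    )
    fit_df = pd.DataFrame(
        [
            {
                "d_break_nm": fit.d_break_nm,
                "c_plateau": fit.c_plateau,
                "c_surface": fit.c_surface,
                "ci_low_nm": fit.ci_low_nm,
                "ci_high_nm": fit.ci_high_nm,
                "n": fit.n,
                "damage_detected": fit.damage_detected,
            }
        ]
    )
    _write_csv(fit_df, out / "damage_fit.csv", cfg)
    io.write_particles(normed, out / "particles_ccnorm.star")
    return {"groups": groups, "overlap": overlap, "damage_fit": fit}


def run_quality_comparison(cfg: PipelineConfig) -> dict:
    """High-quality selection versus size-matched random selections.

    The high-quality set keeps particles from lamellae thinner than the
    thickness cutoff and deeper than the damage layer; comparison sets of
    identical size are drawn randomly, both particle-wise and
    tomogram-wise.
    """
    table, _ = _load_particles(cfg)
    out = cfg.out_dir / "quality"
    out.mkdir(parents=True, exist_ok=True)
    hq, breakdown = curation.select_high_quality(
        table, cfg.thickness_max_nm, cfg.depth_min_nm
    )
    if hq.empty:
        raise ValueError("high-quality filter retained no particles")
    n = len(hq)
    rand_particles = table.sample(n=n, random_state=cfg.seed).sort_index()
    rand_tomo = curation.select_by_tomogram(table, n, seed=cfg.seed)
    io.write_particles(hq, out / "high_quality.star")
    io.write_particles(rand_particles, out / "random_particles.star")
    io.write_particles(rand_tomo, out / "random_tomograms.star")
    summary = pd.DataFrame(
        [
            {
                "set": name,
                "n": len(df),
                "n_tomograms": df["tomogram_id"].nunique(),
                "mean_thickness_nm": df["local_thickness_nm"].mean(),
                "mean_depth_nm": df["depth_nm"].mean(),
            }
            for name, df in (
                ("high_quality", hq),
                ("random_particles", rand_particles),
                ("random_tomograms", rand_tomo),
            )
        ]
    )
    _write_csv(summary, out / "summary.csv", cfg)
    _write_csv(breakdown, out / "per_tomogram.csv", cfg)
    return {"high_quality": hq, "summary": summary, "breakdown": breakdown}


def run_demo(out_dir: str | Path, seed: int = 7) -> dict:
    """Run all three analyses on a bundled synthetic scenario."""
    scenario = synthetic.LamellaScenario(seed=seed)
    cfg = PipelineConfig(out_dir=Path(out_dir), seed=seed, scenario=scenario)
    results = {
        "thickness": run_thickness_analysis(cfg),
        "depth": run_depth_analysis(cfg),
        "quality": run_quality_comparison(cfg),
    }
    logger.info("demo complete; outputs in %s", out_dir)
    return results
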