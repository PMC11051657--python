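"""Reading and writing of particle tables, tomogram metadata and density maps.

Particle tables use the RELION 3.1 particle STAR dialect.  Internally a
table is a :class:`pandas.DataFrame` with canonical column names
(``tomogram_id``, ``x``, ``y``, ``z``, ``rot``, ``tilt``, ``psi``,
``cc_score`` plus any derived columns such as ``depth_nm``); unknown STAR
columns are carried through untouched and restored on write.

Volumes are MRC/CCP4 maps (mode 2 float) handled through gemmi.
"""

from __future__ import annotations

import math
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

# canonical name <-> RELION tag
RELION_COLUMNS: dict[str, str] = {
    "x": "_rlnCoordinateX",
    "y": "_rlnCoordinateY",
    "z": "_rlnCoordinateZ",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
    "tomogram_id": "_rlnMicrographName",
    "cc_score": "_rlnAutopickFigureOfMerit",
}
_TAG_TO_CANONICAL = {v: k for k, v in RELION_COLUMNS.items()}

_NUMERIC_CANONICAL = {"x", "y", "z", "rot", "tilt", "psi", "cc_score"}


class ParticleTableError(ValueError):
    """Raised when a STAR file cannot be interpreted as a particle table."""


def read_particles(path: str | Path) -> pd.DataFrame:
    """Read a RELION 3.1 particle STAR file into a DataFrame.

    Known columns are renamed to canonical names; extra columns keep their
    STAR tags (leading underscore stripped) and are preserved by
    :func:`write_particles`.
    """
    doc = gemmi.cif.read_file(str(path))
    block = _find_particle_block(doc)
    loop = None
    for item in block:
        if item.loop is not None:
            loop = item.loop
            break
    if loop is None:
        raise ParticleTableError(f"no loop_ data found in {path}")
    values = np.array(loop.values, dtype=object).reshape(loop.length(), loop.width())
    df = pd.DataFrame(values, columns=list(loop.tags))
    rename = {}
    for tag in df.columns:
        if tag in _TAG_TO_CANONICAL:
            rename[tag] = _TAG_TO_CANONICAL[tag]
        elif tag.startswith("_lk"):
            rename[tag] = _snake(tag[3:])
        else:
            rename[tag] = tag.lstrip("_")
    df = df.rename(columns=rename)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if not converted.isna().any():
            df[col] = converted
    for col in _NUMERIC_CANONICAL & set(df.columns):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    _validate_particles(df, path)
    return df


def _find_particle_block(doc: "gemmi.cif.Document"):
    for block in doc:
        if any(item.loop is not None for item in block):
            if block.name in ("particles", "") or block.find_loop("_rlnCoordinateX"):
                return block
    raise ParticleTableError("no particle data block found")


def _validate_particles(df: pd.DataFrame, path) -> None:
    for col in ("x", "y", "z"):
        if col in df.columns and not np.isfinite(df[col].to_numpy(float)).all():
            raise ParticleTableError(f"non-finite {col} coordinate in {path}")


def write_particles(df: pd.DataFrame, path: str | Path, block_name: str = "particles") -> None:
    """Write a particle DataFrame as a RELION 3.1 STAR file."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    tags = []
    for col in df.columns:
        if col in RELION_COLUMNS:
            tags.append(RELION_COLUMNS[col])
        elif col.startswith("rln"):
            tags.append("_" + col)
        else:
            tags.append("_lk" + _camel(col))
    loop = block.init_loop("", tags)
    for row in df.itertuples(index=False):
        loop.add_row([_fmt(v) for v in row])
    doc.write_file(str(path))


def _camel(name: str) -> str:
    return "".join(part.capitalize() for part in name.split("_"))


def _snake(name: str) -> str:
    out = []
    for ch in name:
        if ch.isupper() and out:
            out.append("_")
        out.append(ch.lower())
    return "".join(out)


def _fmt(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "1" if v else "0"
    if isinstance(v, (float, np.floating)):
        if math.isnan(v):
            return "nan"
        return f"{v:.6f}"
    s = str(v)
    return s if s and " " not in s else gemmi.cif.quote(s)


def read_tomogram_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-tomogram metadata from a whitespace/tab-delimited table.

    Expected columns: ``tomogram_id`` and ``pixel_size_a`` (Å per voxel);
    optional ``thickness_nm`` (manually measured local thickness) and
    ``position`` (front-to-back label or coordinate in nm).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if "tomogram_id" not in df.columns or "pixel_size_a" not in df.columns:
        raise ValueError(
            f"{path}: tomogram metadata needs 'tomogram_id' and 'pixel_size_a' columns"
        )
    if (df["pixel_size_a"] <= 0).any():
        raise ValueError(f"{path}: pixel_size_a must be positive")
    return df


def read_map(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC/CCP4 map; returns (array, pixel size in Å)."""
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True).astype(np.float32)
    pixel = m.grid.unit_cell.a / m.grid.nu
    return arr, float(pixel)


def write_map(path: str | Path, arr: np.ndarray, pixel_size: float) -> None:
    """Write a float32 MRC/CCP4 map with the given pixel size (Å)."""
    g = gemmi.Ccp4Map()
    g.grid = gemmi.FloatGrid(np.ascontiguousarray(arr, dtype=np.float32))
    nx, ny, nz = arr.shape
    g.grid.unit_cell = gemmi.UnitCell(
        nx * pixel_size, ny * pixel_size, nz * pixel_size, 90, 90, 90
    )
    g.update_ccp4_header()
    g.write_ccp4_map(str(path))
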