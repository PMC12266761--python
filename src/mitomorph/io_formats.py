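"""On-disk formats: multi-page TIFF label stacks, metric CSVs, run configs
and OBJ surface meshes.

Conventions (used everywhere): arrays are (z, y, x) with page order = z;
CSVs are comma-separated UTF-8 with '.' decimals and units embedded in the
column headers (``volume_um3``, ``surface_um2``); readers reject malformed
input rather than coerce.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import DEFAULT_SPACING, LabelImage, LabelVolume


class FormatError(ValueError):
    """Malformed on-disk input."""


def read_label_volume(path, spacing=DEFAULT_SPACING) -> LabelVolume:
    """Read a multi-page TIFF of integer labels; page order becomes z."""
    data = tifffile.imread(str(path))
    if data.size == 0:
        raise FormatError(f"{path}: empty TIFF stack")
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"{path}: label TIFF must be integer-typed, got {data.dtype}")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a single-channel z-stack, got shape {data.shape}")
    return LabelVolume(data, spacing)


def write_label_volume(path, volume: LabelVolume) -> None:
    data = volume.data
    if data.max() > np.iinfo(np.uint16).max:
        raise FormatError("more than 65535 labels; uint16 TIFF cannot hold them")
    tifffile.imwrite(str(path), data.astype(np.uint16))


def read_label_image(path, spacing=(0.005, 0.005)) -> LabelImage:
    data = tifffile.imread(str(path))
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"{path}: label TIFF must be integer-typed, got {data.dtype}")
    if data.ndim != 2:
        raise FormatError(f"{path}: expected a 2D label image, got shape {data.shape}")
    return LabelImage(data, spacing)


def write_label_image(path, image: LabelImage) -> None:
    tifffile.imwrite(str(path), image.data.astype(np.uint16))


def write_metrics_table(records: pd.DataFrame, path, allow_empty: bool = False,
                        key_cols=("patient_id", "label")) -> None:
    """Write a per-organelle metrics CSV with a stable column order.

    Duplicate (patient_id, label) keys are an error — they would silently
    merge distinct organelles downstream.
    """
    if records.empty and not allow_empty:
        raise ValueError("refusing to write an empty metrics table "
                         "(pass allow_empty=True to override)")
    keys = [c for c in key_cols if c in records.columns]
    if keys and len(records) and records.duplicated(subset=keys).any():
        dupes = records.loc[records.duplicated(subset=keys), keys]
        raise ValueError(f"duplicate keys in metrics table: {dupes.values.tolist()}")
    records.to_csv(path, index=False)


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    outdir: str = "mitomorph_out"
    seed: int = 0
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING  # (z, y, x) µm
    input_volumes: list = field(default_factory=list)  # (patient_id, group, path)
    connectivity: int = 3
    min_size: int = 1
    perimeter_mode: str = "mean"
    exclude_edge: bool = False
    fdr_q: float = 0.05
    alpha: float = 0.05
    n_bins: int = 10  # mito-typing columns
    # simulation block (used by `mitomorph simulate`)
    n_young: int = 5
    n_old: int = 4
    organelles_per_patient: int = 250
    volume_shift: float = 1.5
    elongation_shift: float = 0.6
    grid_shape: tuple[int, int, int] = (50, 384, 384)

    def __post_init__(self):
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be 3 positive floats, got {self.voxel_spacing}")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run config; referenced input paths must exist."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(payload) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    if "voxel_spacing" not in payload:
        # every 3D metric depends on it; a silent default would be a trap
        raise FormatError(f"{path}: config must state voxel_spacing explicitly (z, y, x in um)")
    cfg = RunConfig(**payload)
    for entry in cfg.input_volumes:
        p = entry[2] if isinstance(entry, (list, tuple)) else entry["path"]
        if not Path(p).exists():
            raise FormatError(f"config references missing input: {p}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    payload = {k: getattr(cfg, k) for k in RunConfig.__dataclass_fields__}
    payload["voxel_spacing"] = list(cfg.voxel_spacing)
    payload["grid_shape"] = list(cfg.grid_shape)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# Mesh export
# ---------------------------------------------------------------------------

def mesh_is_watertight(faces: np.ndarray) -> bool:
    """Every edge shared by exactly two faces (closed 2-manifold test)."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume via the divergence theorem (signed tetrahedra)."""
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def export_mesh(verts: np.ndarray, faces: np.ndarray, path) -> bool:
    """Write an OBJ triangle mesh (vertex coordinates in µm).

    Returns True when the mesh is watertight; an open surface is still
    written but triggers a warning and a False flag.
    """
    verts = np.asarray(verts, dtype=float)
    faces = np.asarray(faces, dtype=int)
    if verts.size == 0 or faces.size == 0:
        raise ValueError("empty mesh")
    watertight = mesh_is_watertight(faces)
    if not watertight:
        warnings.warn(f"{path}: exported surface is not watertight", stacklevel=2)
    lines = ["# mitomorph surface mesh (units: um)"]
    if not watertight:
        lines.append("# WARNING: open surface (not watertight)")
    lines += [f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}" for v in verts]
    lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in faces]
    Path(path).write_text("\n".join(lines) + "\n")
    return watertight
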