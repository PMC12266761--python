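"""Mito-typing: volume-ordered galleries of representative organelles.

One row per patient, one column per volume quantile; each cell shows the
silhouette of the organelle whose volume is nearest that quantile of the
patient's own volume distribution. Rows are therefore comparable across
patients with different organelle counts, and scanning a row left to right
walks the patient's volume distribution from smallest to largest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import LabelVolume
from .morph3d import ObjectView, extract_objects


@dataclass
class MitotypeGrid:
    manifest: pd.DataFrame  # patient_id, bin, label, volume_um3, padded
    thumbnails: dict  # (patient_id, bin) -> 2D silhouette array
    n_bins: int


def select_representatives(records: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Pick the nearest-to-quantile organelle per volume bin per patient.

    Bin b targets the (b + 0.5)/n_bins quantile. Ties break on the smaller
    label id. Patients with fewer records than bins get padded rows
    (``padded=True``, repeating their extremes); patients with zero records
    are omitted with a warning.
    """
    rows = []
    targets = (np.arange(n_bins) + 0.5) / n_bins
    for pid, grp in records.groupby("patient_id", sort=True):
        grp = grp.sort_values(["volume_um3", "label"]).reset_index(drop=True)
        if grp.empty:
            warnings.warn(f"patient {pid}: no records, omitted from mito-typing")
            continue
        padded = len(grp) < n_bins
        vols = grp["volume_um3"].to_numpy()
        for b, t in enumerate(targets):
            q = np.quantile(vols, t)
            idx = int(np.argmin(np.abs(vols - q)))  # first minimum = smallest label
            rows.append(
                {
                    "patient_id": pid,
                    "bin": b,
                    "label": int(grp.loc[idx, "label"]),
                    "volume_um3": float(vols[idx]),
                    "padded": padded,
                }
            )
    manifest = pd.DataFrame(rows, columns=["patient_id", "bin", "label",
                                           "volume_um3", "padded"])
    if not manifest.empty:
        # per-row volumes must be non-decreasing left to right
        assert (
            manifest.sort_values(["patient_id", "bin"])
            .groupby("patient_id")["volume_um3"]
            .apply(lambda v: bool((np.diff(v) >= -1e-12).all()))
            .all()
        )
    return manifest


def render_thumbnail(obj: ObjectView, axis: int = 0) -> np.ndarray:
    """Maximum-intensity silhouette projection of one organelle."""
    if obj.n_voxels == 0:
        raise ValueError("empty object")
    return obj.mask.max(axis=axis).astype(np.uint8)


def build_mitotype_grid(
    volumes: dict[str, LabelVolume],
    records: pd.DataFrame,
    n_bins: int = 10,
    axis: int = 0,
) -> MitotypeGrid:
    """Assemble the grid: representative selection plus silhouette tiles.

    ``volumes`` maps patient_id to its label volume; ``records`` is the
    per-organelle metrics table (needs patient_id, label, volume_um3).
    """
    manifest = select_representatives(records, n_bins=n_bins)
    thumbs: dict = {}
    for pid, grp in manifest.groupby("patient_id"):
        lv = volumes[pid]
        wanted = set(grp["label"])
        objs = {o.label: o for o in extract_objects(lv) if o.label in wanted}
        for _, row in grp.iterrows():
            thumbs[(pid, int(row["bin"]))] = render_thumbnail(objs[int(row["label"])], axis=axis)
    return MitotypeGrid(manifest, thumbs, n_bins)


def plot_mitotype_grid(grid: MitotypeGrid, path, groups: dict[str, str] | None = None,
                       spacing: tuple[float, float] | None = None,
                       scale_bar_um: float = 0.5) -> None:
    """Render the montage to PNG; one row per patient in manifest order.

    ``spacing`` is the in-plane (y, x) pixel pitch of the silhouettes in µm;
    when given, each tile carries a ``scale_bar_um``-long bar.
    """
    pids = list(pd.unique(grid.manifest["patient_id"]))
    if not pids:
        raise ValueError("empty mito-typing manifest")
    n_rows, n_cols = len(pids), grid.n_bins
    fig, axes = plt.subplots(n_rows, n_cols,
                             figsize=(1.1 * n_cols, 1.1 * n_rows), squeeze=False)
    for i, pid in enumerate(pids):
        for b in range(n_cols):
            ax = axes[i][b]
            ax.set_axis_off()
            tile = grid.thumbnails.get((pid, b))
            if tile is not None:
                ax.imshow(tile, cmap="gray_r", interpolation="nearest")
                if spacing is not None:
                    bar_px = scale_bar_um / spacing[1]
                    h, w = tile.shape
                    ax.plot([w * 0.05, w * 0.05 + bar_px],
                            [h * 0.95, h * 0.95], "k-", lw=1.5)
        name = f"{pid} ({groups[pid]})" if groups and pid in groups else pid
        axes[i][0].set_axis_on()
        axes[i][0].set_ylabel(name, fontsize=7, rotation=0, ha="right", va="center")
        axes[i][0].set_xticks([])
        axes[i][0].set_yticks([])
    title = "Mito-typing: organelles by volume quantile"
    if spacing is not None:
        title += f" (bar = {scale_bar_um:g} µm)"
    fig.suptitle(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "mitomorph"})
    plt.close(fig)
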