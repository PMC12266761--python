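"""Per-organelle 3D morphometrics from instance-label volumes.

Metric panel per mitochondrion:

* volume ``V`` — voxel count × voxel volume (exact for the mask),
* surface area ``SA`` — area of a triangulated isosurface of the binary
  mask, Taubin-smoothed to remove voxel staircase jitter,
* mean slice perimeter — mean in-plane sub-pixel contour length over the
  z-slices the object occupies,
* sphericity ``psi = pi^(1/3) (6V)^(2/3) / SA`` (1 for a sphere),
* mitochondrial complexity index ``MCI = SA^3 / (16 pi^2 V^2) = psi^-3``
  (1 for a sphere, larger for elongated/branched bodies).

Estimator notes: plain marching cubes on a binary mask overestimates the
area of smooth bodies by ~8–9% (staircase jitter), which would bias psi and
MCI; Taubin's shrink-free mesh smoothing removes the jitter without the
systematic shrinkage of Laplacian smoothing, leaving sphere errors under 1%
across radii. Meshes are built in index space and scaled by the (possibly
anisotropic) voxel spacing afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from skimage import measure

from .core import LabelVolume, QCReport

#: Discretization tolerance on psi <= 1 and MCI >= 1, set from the worst
#: observed overshoot on the phantom radius ladder (see tests).
PSI_EPS = 0.02
MCI_EPS = 0.06

TAUBIN_LAMBDA = 0.5
TAUBIN_MU = -0.53
TAUBIN_ITER = 20

PERIMETER_MODES = ("mean", "max", "sum")


@dataclass
class ObjectView:
    """One extracted organelle: a binary mask crop plus its placement."""

    label: int
    mask: np.ndarray  # tight boolean crop, (z, y, x)
    offset: tuple[int, int, int]  # crop origin in volume indices
    touches_edge: bool

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def n_slices(self) -> int:
        return int(self.mask.shape[0])

    @property
    def is_thin(self) -> bool:
        """Thinner than 2 voxels along some axis — isosurface low-confidence."""
        return min(self.mask.shape) < 2


def extract_objects(
    volume: LabelVolume,
    min_size: int = 0,
    connectivity: int = 3,
    qc: QCReport | None = None,
) -> list[ObjectView]:
    """Split a label volume into per-organelle objects.

    Instance labels are taken at face value (two touching labels stay two
    objects). A binary mask (single nonzero label = 1 everywhere) falls back
    to connected components with the configured connectivity (3 = 26-conn).
    Objects under ``min_size`` voxels are dropped and counted in QC.
    """
    qc = qc if qc is not None else QCReport()
    data = volume.data
    labels = volume.labels
    if labels.size == 0:
        qc.warnings.append("empty volume: no labeled voxels")
        return []
    if labels.size == 1 and labels[0] == 1:
        # binary mask: run connected components
        structure = ndimage.generate_binary_structure(3, connectivity)
        data, _ = ndimage.label(data > 0, structure=structure)
        labels = np.unique(data)
        labels = labels[labels != 0]
    qc.n_input_labels = int(labels.size)

    objects: list[ObjectView] = []
    slices = ndimage.find_objects(data)
    for lab in labels:
        sl = slices[int(lab) - 1]
        if sl is None:
            continue
        mask = data[sl] == lab
        n = int(mask.sum())
        if n < min_size:
            qc.n_filtered_small += 1
            continue
        offset = tuple(s.start for s in sl)
        touches = any(
            s.start == 0 or s.stop == dim for s, dim in zip(sl, data.shape)
        )
        ov = ObjectView(int(lab), mask, offset, touches)
        if touches:
            qc.edge_touching.append(int(lab))
        if ov.is_thin:
            qc.thin_flagged.append(int(lab))
        objects.append(ov)
    qc.n_kept = len(objects)
    return objects


def volume_of(obj: ObjectView, spacing) -> float:
    """Voxel-count volume in µm³ — exact for the mask, no mesh involved."""
    if obj.n_voxels == 0:
        raise ValueError("empty object")
    sz, sy, sx = spacing
    return obj.n_voxels * sz * sy * sx


def _taubin_smooth(verts: np.ndarray, faces: np.ndarray,
                   lam: float = TAUBIN_LAMBDA, mu: float = TAUBIN_MU,
                   n_iter: int = TAUBIN_ITER) -> np.ndarray:
    """Shrink-free two-pass Laplacian (Taubin) smoothing of a triangle mesh."""
    n = len(verts)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    avg = sparse.diags(1.0 / deg) @ adj
    v = verts.astype(float).copy()
    for _ in range(n_iter):
        v += lam * (avg @ v - v)
        v += mu * (avg @ v - v)
    return v


def mesh_of(obj: ObjectView, spacing, smooth: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated surface of the object in physical µm coordinates.

    Marching cubes at the 0.5 level of the zero-padded binary mask, then
    Taubin smoothing in index space, then anisotropic scaling to µm.
    """
    if obj.n_voxels == 0:
        raise ValueError("empty object")
    padded = np.pad(obj.mask, 2).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    if smooth:
        verts = _taubin_smooth(verts, faces)
    verts = verts * np.asarray(spacing, dtype=float)
    return verts, faces


def surface_area_of(obj: ObjectView, spacing, smooth: bool = True) -> float:
    """Isosurface area in µm² (see module notes on the estimator)."""
    verts, faces = mesh_of(obj, spacing, smooth=smooth)
    return float(measure.mesh_surface_area(verts, faces))


def _contour_length(mask2d: np.ndarray, spacing2d) -> float:
    """Total sub-pixel contour length of a 2D mask, anisotropy-aware.

    Marching squares at 0.5 on a Gaussian-smoothed copy of the mask. The
    smoothing width scales with object size, sigma = clip(0.5 sqrt(r_eq),
    1, 3) px with r_eq the equivalent-circle radius: a fixed sigma leaves a
    constant staircase-ripple bias (~0.4% at sigma 1) that stops the
    measured perimeter from converging to the true one at high resolution,
    while a size-scaled sigma drives both the ripple and the curvature bias
    (O(sigma^2/r^2)) to zero as resolution grows. Objects too thin to
    survive smoothing (max < 0.5) fall back to the binary mask.
    """
    r_eq = np.sqrt(mask2d.sum() / np.pi)
    sigma = float(np.clip(0.5 * np.sqrt(r_eq), 1.0, 3.0))
    padded = np.pad(mask2d, int(3 * sigma) + 2).astype(np.float32)
    smoothed = ndimage.gaussian_filter(padded, sigma)
    if smoothed.max() <= 0.5:
        smoothed = ndimage.gaussian_filter(padded, 1.0)
    field = smoothed if smoothed.max() > 0.5 else padded
    total = 0.0
    sy, sx = spacing2d
    for contour in measure.find_contours(field, 0.5):
        d = np.diff(contour, axis=0) * np.array([sy, sx])
        total += float(np.sqrt((d**2).sum(axis=1)).sum())
    return total


def slice_perimeter_of(obj: ObjectView, spacing, mode: str = "mean") -> float:
    """In-plane contour length per occupied z-slice, reduced by ``mode``.

    The paper-style 3D "perimeter" of a contour-traced organelle: each
    z-slice contributes its total sub-pixel contour length; ``mean`` (the
    default) averages over occupied slices, ``max`` and ``sum`` are
    alternative reductions selectable by config.
    """
    if mode not in PERIMETER_MODES:
        raise ValueError(f"mode must be one of {PERIMETER_MODES}")
    _, sy, sx = spacing
    lengths = [
        _contour_length(obj.mask[z], (sy, sx))
        for z in range(obj.mask.shape[0])
        if obj.mask[z].any()
    ]
    if not lengths:
        raise ValueError("empty object")
    if mode == "mean":
        return float(np.mean(lengths))
    if mode == "max":
        return float(np.max(lengths))
    return float(np.sum(lengths))


def sphericity(V: float, SA: float) -> float:
    """psi = pi^(1/3) (6V)^(2/3) / SA; 1 for a sphere, < 1 otherwise."""
    if V <= 0 or SA <= 0:
        raise ValueError("V and SA must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / SA)


def mci(V: float, SA: float) -> float:
    """Mitochondrial complexity index: MCI = SA^3 / (36 pi V^2) = psi^-3.

    Sphere-normalized surface-to-volume measure: exactly 1 for a sphere,
    larger for elongated or branched bodies, and the exact inverse cube of
    sphericity by construction. Parts of the literature print the constant
    as 16 pi^2 while still claiming a sphere minimum of 1; those two
    statements are incompatible (the 16 pi^2 form gives 9/(4 pi) ~ 0.716
    for a sphere), so this package uses the self-consistent 36 pi constant
    and exposes the 16 pi^2 variant as :func:`mci_16pi2`.
    """
    if V <= 0 or SA <= 0:
        raise ValueError("V and SA must be positive")
    return float(SA**3 / (36.0 * np.pi * V**2))


def mci_16pi2(V: float, SA: float) -> float:
    """Constant-16pi^2 complexity variant SA^3/(16 pi^2 V^2).

    Differs from :func:`mci` by the fixed factor 9/(4 pi); a unit cube gives
    216/(16 pi^2) ~ 1.368. Emitted for comparability with reports that use
    this constant."""
    if V <= 0 or SA <= 0:
        raise ValueError("V and SA must be positive")
    return float(SA**3 / (16.0 * np.pi**2 * V**2))


def quantify_region(
    volume: LabelVolume,
    min_size: int = 0,
    connectivity: int = 3,
    perimeter_mode: str = "mean",
    exclude_edge: bool = False,
    patient_id: str = "",
    smooth: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Full 3D metric panel for every organelle in a label volume.

    Returns one row per surviving object with columns ``patient_id, label,
    volume_um3, surface_um2, perimeter_um, sphericity, mci, sa_to_vol_per_um,
    mean_cross_section_um2, n_slices, n_voxels, thin, touches_edge`` plus a
    QC report. ``sa_to_vol_per_um`` is the raw SA/V ratio (1/µm) and
    ``mean_cross_section_um2`` the mean occupied-slice cross-sectional area,
    emitted as auxiliary columns alongside the dimensionless panel.
    """
    qc = QCReport()
    objects = extract_objects(volume, min_size=min_size,
                              connectivity=connectivity, qc=qc)
    if exclude_edge:
        objects = [o for o in objects if not o.touches_edge]
        qc.n_kept = len(objects)
    sz, sy, sx = volume.spacing
    rows = []
    for obj in objects:
        V = volume_of(obj, volume.spacing)
        SA = surface_area_of(obj, volume.spacing, smooth=smooth)
        P = slice_perimeter_of(obj, volume.spacing, mode=perimeter_mode)
        psi = sphericity(V, SA)
        occupied = [int(obj.mask[z].sum()) for z in range(obj.mask.shape[0]) if obj.mask[z].any()]
        rows.append(
            {
                "patient_id": patient_id,
                "label": obj.label,
                "volume_um3": V,
                "surface_um2": SA,
                "perimeter_um": P,
                "sphericity": psi,
                "mci": mci(V, SA),
                "sa_to_vol_per_um": SA / V,
                "mean_cross_section_um2": float(np.mean(occupied)) * sy * sx,
                "n_slices": sum(1 for _ in occupied),
                "n_voxels": obj.n_voxels,
                "thin": obj.is_thin,
                "touches_edge": obj.touches_edge,
            }
        )
    columns = [
        "patient_id", "label", "volume_um3", "surface_um2", "perimeter_um",
        "sphericity", "mci", "sa_to_vol_per_um", "mean_cross_section_um2",
        "n_slices", "n_voxels", "thin", "touches_edge",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return df, qc
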