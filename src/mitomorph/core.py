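"""Core containers shared across the pipeline.

Coordinate convention (used everywhere): arrays are indexed ``(z, y, x)``,
0-based; the physical position of voxel ``(i, j, k)`` is
``(i * sz, j * sy, k * sx)`` in micrometres, where ``spacing = (sz, sy, sx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default SBF-SEM voxel pitch in µm, (z, y, x). The z-step (cutting axis)
#: is coarser than the lateral pixel pitch.
DEFAULT_SPACING = (0.09, 0.05, 0.05)


@dataclass
class LabelVolume:
    """A 3D instance-segmentation volume with physical voxel spacing.

    ``data[i, j, k] == L`` means voxel (i, j, k) belongs to organelle ``L``;
    0 is background.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label volume must be integer-typed, got {self.data.dtype}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        sz, sy, sx = self.spacing
        return sz * sy * sx

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        labs = np.unique(self.data)
        return labs[labs != 0]


@dataclass
class LabelImage:
    """A 2D instance-segmentation image with pixel spacing (y, x) in µm."""

    data: np.ndarray
    spacing: tuple[float, float] = (0.005, 0.005)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"label image must be 2D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label image must be integer-typed, got {self.data.dtype}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 2 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 2 positive floats, got {self.spacing}")

    @property
    def pixel_area(self) -> float:
        sy, sx = self.spacing
        return sy * sx


@dataclass
class QCReport:
    """Bookkeeping emitted alongside metric tables."""

    n_input_labels: int = 0
    n_kept: int = 0
    n_filtered_small: int = 0
    thin_flagged: list = field(default_factory=list)
    edge_touching: list = field(default_factory=list)
    orphans: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input_labels": self.n_input_labels,
            "n_kept": self.n_kept,
            "n_filtered_small": self.n_filtered_small,
            "thin_flagged": list(self.thin_flagged),
            "edge_touching": list(self.edge_touching),
            "orphans": list(self.orphans),
            "warnings": list(self.warnings),
        }
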