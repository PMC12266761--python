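"""Synthetic voxel phantoms with analytic ground truth.

The generator emulates what manual contour segmentation of SBF-SEM stacks
produces downstream: an integer instance-label volume of ~50 orthoslices
containing a few hundred organelles, each a non-overlapping solid that never
touches the region boundary (so no object is truncated). Sizes are drawn
log-normally — organelle sizes are strictly positive and right-skewed — and
every organelle carries its analytic volume and surface area so the voxel
estimators can be validated without external data.

Two-cohort studies are simulated by shifting the "old" group's size scale up
and its elongation down, reproducing the qualitative aging phenotype
(larger, rounder, less complex mitochondria) with tunable effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_SPACING, LabelImage, LabelVolume
from .geometry import (
    Branched,
    Capsule,
    Ellipsoid,
    Shape,
    Sphere,
    Torus,
    ellipse_area,
    ellipse_perimeter,
    random_rotation,
)

SHAPE_FAMILIES = ("sphere", "ellipsoid", "tube", "branched", "torus")

#: Default size parameters, physical µm. Medians chosen for intermyofibrillar
#: mitochondria (~0.1–1 µm³): log-normal radii around 0.3 µm, tubes ~1.2 µm
#: long, mild dispersion.
DEFAULT_SIZE_PARAMS: dict = {
    "sphere": {"radius_median": 0.30, "radius_sigma": 0.25},
    "ellipsoid": {
        "minor_median": 0.25,
        "minor_sigma": 0.25,
        "elongation_median": 2.0,
        "elongation_sigma": 0.30,
    },
    "tube": {"radius_median": 0.18, "radius_sigma": 0.20, "length_median": 1.2, "length_sigma": 0.30},
    "branched": {"radius_median": 0.16, "radius_sigma": 0.15, "arm_median": 0.7, "arm_sigma": 0.25},
    "torus": {"major_median": 0.35, "major_sigma": 0.15, "minor_median": 0.12, "minor_sigma": 0.15},
}

#: Mixture over families used when ``shape_family="mixed"``; ellipsoids
#: dominate, matching the mostly-elongated phenotype of young muscle.
DEFAULT_FAMILY_MIX: dict = {
    "sphere": 0.25,
    "ellipsoid": 0.45,
    "tube": 0.20,
    "branched": 0.05,
    "torus": 0.05,
}

MAX_PLACEMENT_ATTEMPTS = 1000


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an organelle."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of one synthetic region of interest."""

    shape_family: str = "mixed"  # one family name or "mixed"
    count: int = 250
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING  # (z, y, x) µm
    grid_shape: tuple[int, int, int] = (50, 384, 384)  # (z, y, x) voxels
    size_params: dict = field(default_factory=lambda: DEFAULT_SIZE_PARAMS)
    family_mix: dict = field(default_factory=lambda: DEFAULT_FAMILY_MIX)
    seed: int = 0

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("grid too small")
        if self.shape_family != "mixed" and self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape family {self.shape_family!r}")


@dataclass(frozen=True)
class CohortSimSpec:
    """Two-cohort study design with multiplicative 'old' effect shifts."""

    n_patients_per_group: tuple[int, int] = (5, 4)  # (young, old)
    organelles_per_patient: int = 250
    volume_shift: float = 1.5  # old-group volume scale, >= 1 mimics aging
    elongation_shift: float = 0.6  # old-group elongation scale, <= 1 mimics aging
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    grid_shape: tuple[int, int, int] = (50, 384, 384)
    seed: int = 0

    def __post_init__(self):
        if self.volume_shift <= 0 or self.elongation_shift <= 0:
            raise ValueError("effect shifts must be positive")
        if self.organelles_per_patient < 1:
            raise ValueError("organelles_per_patient must be >= 1")


#: log-normal draws are truncated at +/- this many sigma (log space): an
#: organelle taller than the imaged slab could never appear untruncated in a
#: real ROI, and the generator guarantees no object touches the boundary
LOGNORMAL_CLIP_SIGMA = 2.5


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    z = float(np.clip(rng.normal(), -LOGNORMAL_CLIP_SIGMA, LOGNORMAL_CLIP_SIGMA))
    return float(median * np.exp(sigma * z))


def _draw_shape(family: str, params: dict, rng: np.random.Generator) -> Shape:
    p = params[family]
    if family == "sphere":
        return Sphere(_lognormal(rng, p["radius_median"], p["radius_sigma"]))
    if family == "ellipsoid":
        b = _lognormal(rng, p["minor_median"], p["minor_sigma"])
        elong = max(1.0, _lognormal(rng, p["elongation_median"], p["elongation_sigma"]))
        c = b * float(rng.uniform(0.85, 1.0))  # slightly triaxial
        return Ellipsoid((elong * b, b, c), rot=random_rotation(rng))
    if family == "tube":
        r = _lognormal(rng, p["radius_median"], p["radius_sigma"])
        L = _lognormal(rng, p["length_median"], p["length_sigma"])
        return Capsule(r, L, rot=random_rotation(rng))
    if family == "branched":
        r = _lognormal(rng, p["radius_median"], p["radius_sigma"])
        n_arms = int(rng.integers(3, 5))
        dirs = rng.normal(size=(n_arms, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        lengths = [_lognormal(rng, p["arm_median"], p["arm_sigma"]) for _ in range(n_arms)]
        return Branched(r, lengths, dirs, seed=int(rng.integers(2**31)))
    if family == "torus":
        R = _lognormal(rng, p["major_median"], p["major_sigma"])
        r = min(_lognormal(rng, p["minor_median"], p["minor_sigma"]), 0.8 * R)
        return Torus(R, r, rot=random_rotation(rng))
    raise ValueError(f"unknown family {family!r}")


def _draw_population(spec: PhantomSpec, rng: np.random.Generator,
                     scale: float = 1.0, elongation_scale: float = 1.0) -> list[tuple[str, Shape]]:
    """Draw ``spec.count`` shapes (no placement), largest-first.

    Largest-first is the placement order (big shapes are near-impossible to
    fit into an already crowded region, small ones slot into gaps), and
    sorting here keeps ground truth identical whether or not the population
    is subsequently voxelized.
    """
    families = list(spec.family_mix) if spec.shape_family == "mixed" else [spec.shape_family]
    probs = None
    if spec.shape_family == "mixed":
        probs = np.array([spec.family_mix[f] for f in families], dtype=float)
        probs /= probs.sum()
    params = _scaled_params(spec.size_params, scale, elongation_scale)
    drawn: list[tuple[str, Shape]] = []
    for _ in range(spec.count):
        fam = families[0] if probs is None else str(rng.choice(families, p=probs))
        drawn.append((fam, _draw_shape(fam, params, rng)))
    drawn.sort(key=lambda t: -t[1].bounding_radius)
    return drawn


def _place_shapes(spec: PhantomSpec, rng: np.random.Generator,
                  drawn: list[tuple[str, Shape]] | None = None,
                  scale: float = 1.0, elongation_scale: float = 1.0) -> list[tuple[str, Shape]]:
    """Place a drawn population without overlap or boundary contact.

    Placement uses conservative bounding-sphere separation and keeps every
    shape at least one voxel away from the region boundary. ``scale``
    multiplies linear dimensions (so volume scales by ``scale**3``);
    ``elongation_scale`` multiplies ellipsoid/tube elongation.
    """
    extent = np.array(spec.grid_shape) * np.array(spec.voxel_spacing)
    margin_pad = np.array(spec.voxel_spacing)  # 1 voxel clearance off the edge
    if drawn is None:
        drawn = _draw_population(spec, rng, scale, elongation_scale)
    placed: list[tuple[str, Shape]] = []
    centers = np.empty((0, 3))
    radii = np.empty(0)
    for k, (fam, shape) in enumerate(drawn, start=1):
        r = shape.bounding_radius
        lo = r + margin_pad
        hi = extent - r - margin_pad
        if np.any(hi <= lo):
            raise PlacementError(
                f"region too crowded: organelle {k} (bounding radius {r:.3f} um) "
                f"does not fit in extent {extent}"
            )
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            c = rng.uniform(lo, hi)
            if len(centers) == 0 or np.all(
                np.linalg.norm(centers - c, axis=1) > radii + r
            ):
                shape.center = np.asarray(c)
                if isinstance(shape, Branched):
                    for arm in shape.arms:
                        arm.center = arm.center + c
                placed.append((fam, shape))
                centers = np.vstack([centers, c[None]])
                radii = np.append(radii, r)
                break
        else:
            raise PlacementError(
                f"region too crowded: could not place organelle {k} after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return placed


def _scaled_params(size_params: dict, scale: float, elongation_scale: float) -> dict:
    if scale == 1.0 and elongation_scale == 1.0:
        return size_params
    out = {f: dict(p) for f, p in size_params.items()}
    for fam, p in out.items():
        for key in ("radius_median", "minor_median", "length_median",
                    "arm_median", "major_median"):
            if key in p:
                p[key] = p[key] * scale
        # elongation shifts are volume-preserving so the two effects stay
        # orthogonal: an ellipsoid's volume goes as elongation * minor^3 and
        # a tube's as length * radius^2, so compensate the other dimension
        if fam == "ellipsoid":
            p["elongation_median"] = p["elongation_median"] * elongation_scale
            p["minor_median"] = p["minor_median"] * elongation_scale ** (-1.0 / 3.0)
        if fam == "tube":
            p["length_median"] = p["length_median"] * elongation_scale
            p["radius_median"] = p["radius_median"] * elongation_scale ** (-0.5)
    return out


def _voxelize(placed: list[tuple[str, Shape]], spec: PhantomSpec) -> np.ndarray:
    sz, sy, sx = spec.voxel_spacing
    spacing = np.array([sz, sy, sx])
    vol = np.zeros(spec.grid_shape, dtype=np.uint16)
    for k, (_, shape) in enumerate(placed, start=1):
        r = shape.bounding_radius
        lo_idx = np.maximum(np.floor((shape.center - r) / spacing - 1), 0).astype(int)
        hi_idx = np.minimum(
            np.ceil((shape.center + r) / spacing + 1).astype(int) + 1,
            np.array(spec.grid_shape),
        )
        axes = [np.arange(lo_idx[d], hi_idx[d]) * spacing[d] for d in range(3)]
        Z, Y, X = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([Z.ravel(), Y.ravel(), X.ravel()], axis=1)
        inside = shape.contains(pts).reshape(Z.shape)
        sub = vol[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
        sub[inside] = k
    return vol


def ground_truth_table(placed: list[tuple[str, Shape]]) -> pd.DataFrame:
    rows = [
        {
            "label": k,
            "shape_family": fam,
            "volume_um3": shape.volume,
            "surface_um2": shape.surface_area,
            "gt_method": shape.gt_method,
        }
        for k, (fam, shape) in enumerate(placed, start=1)
    ]
    return pd.DataFrame(rows)


def generate_phantom_volume(spec: PhantomSpec) -> tuple[LabelVolume, pd.DataFrame]:
    """Generate one labeled region and its analytic ground-truth table.

    Label ``k`` in {1..count} marks organelle k; background is 0. Identical
    spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    placed = _place_shapes(spec, rng)
    vol = _voxelize(placed, spec)
    gt = ground_truth_table(placed)
    return LabelVolume(vol, spec.voxel_spacing), gt


# ---------------------------------------------------------------------------
# 2D TEM phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemPhantomSpec:
    """Elliptical 2D mitochondria containing lamellar cristae strips."""

    count: int = 7
    pixel_size: float = 0.005  # µm/px
    image_shape: tuple[int, int] = (768, 768)
    semi_major_median: float = 0.45
    semi_major_sigma: float = 0.25
    aspect_median: float = 1.8
    aspect_sigma: float = 0.25
    cristae_per_mito: tuple[int, int] = (3, 8)  # inclusive range, can be (0, 0)
    crista_rel_width: float = 0.08  # strip half-thickness relative to minor axis
    seed: int = 0

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")


def generate_tem_image(
    spec: TemPhantomSpec,
) -> tuple[LabelImage, LabelImage, pd.DataFrame, pd.DataFrame]:
    """Generate paired mitochondria/cristae label images with ground truth.

    Returns ``(mito_labels, cristae_labels, mito_gt, cristae_gt)``. Every
    crista strip lies wholly inside its parent ellipse (guaranteed by
    construction in ellipse-local coordinates); cristae ground truth carries
    the parent mapping and analytic strip area, and mito ground truth the
    analytic ellipse area and quadrature perimeter.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_shape
    px = spec.pixel_size
    extent = np.array([H, W]) * px
    mito = np.zeros((H, W), dtype=np.uint16)
    cristae = np.zeros((H, W), dtype=np.uint16)
    yy, xx = np.meshgrid(np.arange(H) * px, np.arange(W) * px, indexing="ij")

    mito_rows, cristae_rows = [], []
    centers, radii = np.empty((0, 2)), np.empty(0)
    crista_label = 0
    for k in range(1, spec.count + 1):
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            a = _lognormal(rng, spec.semi_major_median, spec.semi_major_sigma)
            aspect = max(1.0, _lognormal(rng, spec.aspect_median, spec.aspect_sigma))
            b = a / aspect
            theta = rng.uniform(0, np.pi)
            lo, hi = a + px, extent - a - px
            if np.any(hi <= lo):
                continue
            c = rng.uniform(lo, hi)
            if len(centers) and np.any(np.linalg.norm(centers - c, axis=1) <= radii + a):
                continue
            break
        else:
            raise PlacementError(f"field too crowded: could not place mitochondrion {k}")
        centers = np.vstack([centers, c[None]])
        radii = np.append(radii, a)

        ct, st = np.cos(theta), np.sin(theta)
        u = (yy - c[0]) * ct + (xx - c[1]) * st  # along major axis
        v = -(yy - c[0]) * st + (xx - c[1]) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        mito[inside] = k
        mito_rows.append(
            {
                "label": k,
                "area_um2": ellipse_area(a, b),
                "perimeter_um": ellipse_perimeter(a, b),
                "semi_major_um": a,
                "semi_minor_um": b,
            }
        )

        n_cr = int(rng.integers(spec.cristae_per_mito[0], spec.cristae_per_mito[1] + 1))
        half_w = spec.crista_rel_width * b
        # lamellar strips perpendicular to the major axis at offsets u0:
        # strip = {|u - u0| <= half_w} ∩ {|v| <= v_max(u)} with v_max chosen
        # to keep the whole strip strictly inside the ellipse
        offsets = np.linspace(-0.7 * a, 0.7 * a, n_cr) if n_cr else []
        for u0 in offsets:
            u_far = abs(u0) + half_w
            v_max = 0.85 * b * np.sqrt(max(0.0, 1.0 - (u_far / a) ** 2))
            if v_max <= 2 * px:
                continue
            crista_label += 1
            strip = inside & (np.abs(u - u0) <= half_w) & (np.abs(v) <= v_max)
            cristae[strip] = crista_label
            cristae_rows.append(
                {
                    "crista_label": crista_label,
                    "parent_label": k,
                    "area_um2": 2 * half_w * 2 * v_max,  # exact rectangle area
                }
            )

    # construction guarantee: cristae pixels must sit inside their parent
    bad = cristae[(cristae > 0) & (mito == 0)]
    if bad.size:
        raise PlacementError(f"crista escaped its parent ellipse: labels {np.unique(bad)}")
    return (
        LabelImage(mito, (px, px)),
        LabelImage(cristae, (px, px)),
        pd.DataFrame(mito_rows),
        pd.DataFrame(
            cristae_rows, columns=["crista_label", "parent_label", "area_um2"]
        ),
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class PatientSim:
    patient_id: str
    group: str  # "young" | "old"
    volume: LabelVolume | None
    ground_truth: pd.DataFrame


def simulate_cohorts(spec: CohortSimSpec, voxelize: bool = True) -> list[PatientSim]:
    """Simulate a young/old two-cohort study.

    Old-group organelles are drawn with linear dimensions scaled by
    ``volume_shift ** (1/3)`` (so expected volume scales by ``volume_shift``)
    and elongation scaled by ``elongation_shift``. With both shifts at 1 the
    groups are exchangeable. ``voxelize=False`` skips rasterization and
    returns analytic ground truth only — the same organelle populations at a
    fraction of the cost, used for Monte-Carlo calibration of the statistics.
    """
    root = np.random.SeedSequence(spec.seed)
    n_young, n_old = spec.n_patients_per_group
    seeds = root.spawn(n_young + n_old)
    out: list[PatientSim] = []
    base = PhantomSpec(
        shape_family="mixed",
        count=spec.organelles_per_patient,
        voxel_spacing=spec.voxel_spacing,
        grid_shape=spec.grid_shape,
        # branched GT is numeric and slow; cohorts use closed-form families
        family_mix={"sphere": 0.3, "ellipsoid": 0.5, "tube": 0.2},
    )
    for i, seq in enumerate(seeds):
        group = "young" if i < n_young else "old"
        pid = f"{group}_{(i if group == 'young' else i - n_young) + 1:02d}"
        scale = spec.volume_shift ** (1.0 / 3.0) if group == "old" else 1.0
        elong = spec.elongation_shift if group == "old" else 1.0
        rng = np.random.default_rng(seq)
        drawn = _draw_population(base, rng, scale=scale, elongation_scale=elong)
        placed = _place_shapes(base, rng, drawn=drawn) if voxelize else drawn
        gt = ground_truth_table(placed)
        gt.insert(0, "patient_id", pid)
        gt.insert(1, "group", group)
        vol = LabelVolume(_voxelize(placed, base), spec.voxel_spacing) if voxelize else None
        out.append(PatientSim(pid, group, vol, gt))
    return out


def demo_cohort_spec(seed: int = 0) -> CohortSimSpec:
    """The packaged demo study: 5 young + 4 old regions, 250 organelles each."""
    return CohortSimSpec(seed=seed)
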