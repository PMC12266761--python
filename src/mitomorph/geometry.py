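"""Analytic solid primitives used by the phantom generator.

Every shape lives in physical (z, y, x) µm coordinates and provides an
exact (or high-accuracy numeric) volume and surface area, an inside test
evaluated on arrays of points, and a bounding radius used for collision-free
placement. These analytic values are the ground truth against which the
voxel-based estimators are validated, so the numeric paths here (ellipsoid
surface, ellipse perimeter) use quadrature accurate to far better than the
estimator tolerances under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss as _leggauss
from scipy.spatial.transform import Rotation


@lru_cache(maxsize=8)
def leggauss(order: int):
    return _leggauss(order)


def _as_rotation(rot) -> np.ndarray:
    if rot is None:
        return np.eye(3)
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    return rot


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix."""
    return Rotation.random(rng=rng).as_matrix()


class Shape:
    """Base class: a rigid solid at ``center`` with orientation ``rot``."""

    center: np.ndarray
    rot: np.ndarray

    def _to_local(self, pts: np.ndarray) -> np.ndarray:
        return (pts - self.center) @ self.rot

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Boolean inside-test for an (N, 3) array of (z, y, x) µm points."""
        raise NotImplementedError

    @property
    def volume(self) -> float:
        raise NotImplementedError

    @property
    def surface_area(self) -> float:
        raise NotImplementedError

    @property
    def bounding_radius(self) -> float:
        raise NotImplementedError

    #: "exact" for closed forms, "numeric" for quadrature/sampling oracles
    gt_method: str = "exact"


@dataclass
class Sphere(Shape):
    radius: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rot: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        self.center = np.asarray(self.center, dtype=float)
        self.rot = _as_rotation(self.rot)

    def contains(self, pts):
        d = np.asarray(pts, dtype=float) - self.center
        return (d * d).sum(axis=-1) <= self.radius**2

    @property
    def volume(self):
        return 4.0 / 3.0 * np.pi * self.radius**3

    @property
    def surface_area(self):
        return 4.0 * np.pi * self.radius**2

    @property
    def bounding_radius(self):
        return self.radius


def ellipsoid_surface_area(a: float, b: float, c: float, order: int = 64) -> float:
    """Surface area of an ellipsoid with semi-axes a, b, c.

    Gauss–Legendre quadrature of the parametric surface integral; relative
    error < 2e-6 at order 64 up to aspect ratio 10 (and < 1e-13 below
    aspect 2), orders of magnitude better than the voxel estimators this
    serves as oracle for.
    """
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    # parametrize: r(u,v) = (a sin u cos v, b sin u sin v, c cos u)
    xu, wu = leggauss(order)
    u = 0.5 * np.pi * (xu + 1.0)  # map [-1,1] -> [0, pi]
    wu = wu * 0.5 * np.pi
    xv, wv = leggauss(order)
    v = np.pi * (xv + 1.0)  # [0, 2pi]
    wv = wv * np.pi
    U, V = np.meshgrid(u, v, indexing="ij")
    su, cu = np.sin(U), np.cos(U)
    sv, cv = np.sin(V), np.cos(V)
    # |r_u x r_v| for the ellipsoid
    integrand = su * np.sqrt(
        (b * c * su * cv) ** 2 + (a * c * su * sv) ** 2 + (a * b * cu) ** 2
    )
    return float(np.einsum("i,j,ij->", wu, wv, integrand))


@dataclass
class Ellipsoid(Shape):
    semi_axes: tuple[float, float, float]
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rot: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.semi_axes = tuple(float(s) for s in self.semi_axes)
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        self.center = np.asarray(self.center, dtype=float)
        self.rot = _as_rotation(self.rot)

    def contains(self, pts):
        local = self._to_local(np.asarray(pts, dtype=float))
        axes = np.asarray(self.semi_axes)
        return ((local / axes) ** 2).sum(axis=-1) <= 1.0

    @property
    def volume(self):
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def surface_area(self):
        return ellipsoid_surface_area(*self.semi_axes)

    @property
    def bounding_radius(self):
        return max(self.semi_axes)


@dataclass
class Capsule(Shape):
    """Sphero-cylinder: cylinder of ``length`` capped by two hemispheres."""

    radius: float
    length: float  # cylindrical part only
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rot: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        if self.radius <= 0 or self.length < 0:
            raise ValueError("radius must be > 0 and length >= 0")
        self.center = np.asarray(self.center, dtype=float)
        self.rot = _as_rotation(self.rot)

    def contains(self, pts):
        local = self._to_local(np.asarray(pts, dtype=float))
        # axis along local z (first index)
        h = self.length / 2.0
        t = np.clip(local[..., 0], -h, h)
        d2 = (local[..., 0] - t) ** 2 + local[..., 1] ** 2 + local[..., 2] ** 2
        return d2 <= self.radius**2

    @property
    def volume(self):
        return np.pi * self.radius**2 * self.length + 4.0 / 3.0 * np.pi * self.radius**3

    @property
    def surface_area(self):
        return 2.0 * np.pi * self.radius * self.length + 4.0 * np.pi * self.radius**2

    @property
    def bounding_radius(self):
        return self.length / 2.0 + self.radius

    def surface_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform random points on the capsule surface (for union oracles)."""
        a_cyl = 2.0 * np.pi * self.radius * self.length
        a_sph = 4.0 * np.pi * self.radius**2
        n_cyl = rng.binomial(n, a_cyl / (a_cyl + a_sph)) if self.length > 0 else 0
        pts = []
        if n_cyl:
            z = rng.uniform(-self.length / 2, self.length / 2, n_cyl)
            phi = rng.uniform(0, 2 * np.pi, n_cyl)
            pts.append(
                np.stack([z, self.radius * np.cos(phi), self.radius * np.sin(phi)], axis=1)
            )
        n_sph = n - n_cyl
        if n_sph:
            v = rng.normal(size=(n_sph, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            caps = v * self.radius
            caps[:, 0] += np.sign(caps[:, 0]) * self.length / 2.0
            pts.append(caps)
        local = np.concatenate(pts) if pts else np.empty((0, 3))
        return local @ self.rot.T + self.center


@dataclass
class Torus(Shape):
    """Ring torus with tube radius ``minor`` around circle radius ``major``."""

    major: float
    minor: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rot: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        if self.minor <= 0 or self.major <= self.minor:
            raise ValueError("need 0 < minor < major for a ring torus")
        self.center = np.asarray(self.center, dtype=float)
        self.rot = _as_rotation(self.rot)

    def contains(self, pts):
        local = self._to_local(np.asarray(pts, dtype=float))
        rho = np.sqrt(local[..., 1] ** 2 + local[..., 2] ** 2)
        return (rho - self.major) ** 2 + local[..., 0] ** 2 <= self.minor**2

    @property
    def volume(self):
        return 2.0 * np.pi**2 * self.major * self.minor**2

    @property
    def surface_area(self):
        return 4.0 * np.pi**2 * self.major * self.minor

    @property
    def bounding_radius(self):
        return self.major + self.minor


class Branched(Shape):
    """Union of capsule arms radiating from a common junction.

    No closed-form volume/surface exists for the union, so ground truth is
    numeric: volume by fine-grid sampling, surface by Monte-Carlo surface
    sampling with inside-other-component rejection. Tagged ``gt_method =
    "numeric"``; never used as a tight oracle.
    """

    gt_method = "numeric"

    def __init__(self, arm_radius, arm_lengths, directions, center=(0, 0, 0), seed=0):
        if arm_radius <= 0:
            raise ValueError("arm radius must be positive")
        self.center = np.asarray(center, dtype=float)
        self.rot = np.eye(3)
        self.arms: list[Capsule] = []
        for L, d in zip(arm_lengths, directions):
            d = np.asarray(d, dtype=float)
            d = d / np.linalg.norm(d)
            # capsule axis is local z; build rotation sending z -> d
            rot = _rotation_from_z(d)
            arm_center = self.center + d * (L / 2.0)
            self.arms.append(Capsule(arm_radius, L, center=arm_center, rot=rot))
        self._seed = int(seed)
        self._gt_cache: tuple[float, float] | None = None

    def contains(self, pts):
        inside = np.zeros(np.asarray(pts).shape[:-1], dtype=bool)
        for arm in self.arms:
            inside |= arm.contains(pts)
        return inside

    @property
    def bounding_radius(self):
        return max(
            np.linalg.norm(a.center - self.center) + a.bounding_radius for a in self.arms
        )

    def _ground_truth(self) -> tuple[float, float]:
        if self._gt_cache is None:
            rng = np.random.default_rng(self._seed)
            # surface: analytic per-arm area x retained fraction
            sa = 0.0
            for i, arm in enumerate(self.arms):
                pts = arm.surface_points(20000, rng)
                keep = np.ones(len(pts), dtype=bool)
                for j, other in enumerate(self.arms):
                    if j != i:
                        keep &= ~other.contains(pts)
                sa += arm.surface_area * keep.mean()
            # volume: fine grid over the bounding box
            r = self.bounding_radius
            step = min(a.radius for a in self.arms) / 8.0
            ax = [np.arange(c - r, c + r + step, step) for c in self.center]
            vol = 0.0
            for z in ax[0]:  # chunk over z to bound memory
                Y, X = np.meshgrid(ax[1], ax[2], indexing="ij")
                pts = np.stack([np.full(Y.size, z), Y.ravel(), X.ravel()], axis=1)
                vol += self.contains(pts).sum() * step**3
            self._gt_cache = (float(vol), float(sa))
        return self._gt_cache

    @property
    def volume(self):
        return self._ground_truth()[0]

    @property
    def surface_area(self):
        return self._ground_truth()[1]


def _rotation_from_z(d: np.ndarray) -> np.ndarray:
    """Rotation matrix whose local z-axis maps onto unit vector ``d``."""
    z = np.array([1.0, 0.0, 0.0])  # local axis index 0 (z in (z,y,x))
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    # _to_local computes (p - c) @ rot, so columns of rot must be the local
    # basis axes in world coordinates; column 0 of R is R @ e_z = d.
    return R


# ---------------------------------------------------------------------------
# 2D analytic helpers (TEM oracles)
# ---------------------------------------------------------------------------

def ellipse_area(a: float, b: float) -> float:
    return np.pi * a * b


def ellipse_perimeter(a: float, b: float, order: int = 400) -> float:
    """Ellipse circumference by Gauss–Legendre quadrature of the arc-length
    integral (the oracle; deliberately not Ramanujan's approximation)."""
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    x, w = leggauss(order)
    t = 0.25 * np.pi * (x + 1.0)  # one quadrant, [0, pi/2]
    wt = w * 0.25 * np.pi
    ds = np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2)
    return float(4.0 * (wt * ds).sum())
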