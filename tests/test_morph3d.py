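"""3D metric panel: voxel-count volume, isosurface area, slice perimeter,
sphericity and complexity index against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from mitomorph.core import LabelVolume, QCReport
from mitomorph.geometry import ellipsoid_surface_area
from mitomorph.morph3d import (
    ObjectView,
    extract_objects,
    mci,
    mci_16pi2,
    quantify_region,
    slice_perimeter_of,
    sphericity,
    surface_area_of,
    volume_of,
)
from tests.conftest import digitized_sphere_mask, sphere_object


# ---------------------------------------------------------------------------
# object extraction
# ---------------------------------------------------------------------------

def two_sphere_volume(binary: bool):
    a = digitized_sphere_mask(6)
    b = digitized_sphere_mask(3)
    vol = np.zeros((20, 50, 20), dtype=np.uint16)
    vol[1:1 + a.shape[0], 1:1 + a.shape[1], 1:1 + a.shape[2]][a] = 1
    vol[1:1 + b.shape[0], 30:30 + b.shape[1], 1:1 + b.shape[2]][b] = 1 if binary else 2
    return LabelVolume(vol, (1, 1, 1))


def test_binary_mask_falls_back_to_connected_components():
    objs = extract_objects(two_sphere_volume(binary=True))
    assert len(objs) == 2


def test_min_size_filters_and_counts():
    qc = QCReport()
    objs = extract_objects(two_sphere_volume(binary=True), min_size=200, qc=qc)
    assert len(objs) == 1
    assert qc.n_filtered_small == 1


def test_touching_instance_labels_stay_separate():
    vol = np.zeros((5, 10, 5), dtype=np.uint16)
    vol[1:4, 1:5, 1:4] = 1
    vol[1:4, 5:9, 1:4] = 2  # touches label 1 face-on
    objs = extract_objects(LabelVolume(vol, (1, 1, 1)))
    assert sorted(o.label for o in objs) == [1, 2]


def test_empty_volume_warns_and_returns_nothing():
    qc = QCReport()
    objs = extract_objects(LabelVolume(np.zeros((4, 4, 4), np.uint16), (1, 1, 1)), qc=qc)
    assert objs == []
    assert any("empty" in w for w in qc.warnings)


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------

def test_volume_is_voxel_count_times_voxel_volume():
    mask = np.ones((10, 10, 10), dtype=bool)
    obj = ObjectView(1, mask, (0, 0, 0), False)
    assert volume_of(obj, (0.5, 0.5, 0.5)) == pytest.approx(125.0, rel=1e-15)
    single = ObjectView(1, np.ones((1, 1, 1), bool), (0, 0, 0), False)
    assert volume_of(single, (0.09, 0.05, 0.05)) == pytest.approx(0.09 * 0.05 * 0.05)


def test_digitized_sphere_volume_within_2pct():
    obj = sphere_object(10)
    assert volume_of(obj, (1, 1, 1)) == pytest.approx(4 / 3 * np.pi * 1000, rel=0.02)


# ---------------------------------------------------------------------------
# surface area
# ---------------------------------------------------------------------------

def test_sphere_surface_area_within_3pct(sphere15):
    assert surface_area_of(sphere15, (1, 1, 1)) == pytest.approx(
        4 * np.pi * 225, rel=0.03
    )


def test_cuboid_surface_area_within_5pct():
    a, b, c = 40, 30, 24
    obj = ObjectView(1, np.ones((a, b, c), bool), (0, 0, 0), False)
    assert surface_area_of(obj, (1, 1, 1)) == pytest.approx(
        2 * (a * b + b * c + c * a), rel=0.05
    )


def test_anisotropic_spacing_gives_stretched_ellipsoid_area():
    # a sphere mask measured at spacing (2,1,1) is physically a 2:1:1 prolate
    # spheroid; compare to the quadrature oracle
    obj = sphere_object(12)
    got = surface_area_of(obj, (2, 1, 1))
    want = ellipsoid_surface_area(24.0, 12.0, 12.0)
    assert got == pytest.approx(want, rel=0.03)


def test_thin_object_flagged_but_computed():
    mask = np.ones((1, 8, 8), dtype=bool)  # one voxel thick in z
    obj = ObjectView(1, mask, (0, 0, 0), False)
    assert obj.is_thin
    assert surface_area_of(obj, (1, 1, 1)) > 0


# ---------------------------------------------------------------------------
# slice perimeter
# ---------------------------------------------------------------------------

def test_single_slice_circle_perimeter_within_3pct():
    disc = digitized_sphere_mask(10)[:, :, :]  # take the equatorial plane
    c = disc.shape[0] // 2
    mask = disc[c][None]  # a single z-slice containing a radius-10 circle
    obj = ObjectView(1, mask, (0, 0, 0), False)
    assert slice_perimeter_of(obj, (1, 1, 1)) == pytest.approx(2 * np.pi * 10, rel=0.03)


def test_sphere_mean_slice_perimeter_below_equatorial():
    obj = sphere_object(12)
    mean_p = slice_perimeter_of(obj, (1, 1, 1), mode="mean")
    max_p = slice_perimeter_of(obj, (1, 1, 1), mode="max")
    # slices at height z have radius r*sin(theta) <= r, so the mean must sit
    # strictly below the equatorial maximum
    assert mean_p < max_p
    assert max_p == pytest.approx(2 * np.pi * 12, rel=0.04)


def test_thin_rod_perimeter_constant_across_slices():
    mask = np.ones((7, 1, 1), dtype=bool)  # one-voxel-thick vertical rod
    obj = ObjectView(1, mask, (0, 0, 0), False)
    mean_p = slice_perimeter_of(obj, (1, 1, 1), mode="mean")
    sum_p = slice_perimeter_of(obj, (1, 1, 1), mode="sum")
    assert sum_p == pytest.approx(7 * mean_p, rel=1e-12)
    assert mean_p > 0


def test_perimeter_mode_validated():
    with pytest.raises(ValueError):
        slice_perimeter_of(sphere_object(3), (1, 1, 1), mode="median")


# ---------------------------------------------------------------------------
# sphericity and MCI
# ---------------------------------------------------------------------------

def test_sphericity_normalizations():
    assert sphericity(4 * np.pi / 3, 4 * np.pi) == pytest.approx(1.0, rel=1e-12)
    # unit cube: psi = pi^(1/3) * 6^(2/3) / 6 = 0.80600
    assert sphericity(1.0, 6.0) == pytest.approx(0.80600, abs=5e-6)


def test_mci_normalizations():
    assert mci(4 * np.pi / 3, 4 * np.pi) == pytest.approx(1.0, rel=1e-12)
    # unit cube under the self-consistent 36*pi constant: psi^-3
    assert mci(1.0, 6.0) == pytest.approx(216 / (36 * np.pi), rel=1e-12)
    assert mci(1.0, 6.0) == pytest.approx(sphericity(1.0, 6.0) ** -3, rel=1e-12)
    # literature variant with the 16*pi^2 constant: 216/(16 pi^2) ~ 1.368
    assert mci_16pi2(1.0, 6.0) == pytest.approx(216 / (16 * np.pi**2), rel=1e-12)
    assert mci_16pi2(1.0, 6.0) == pytest.approx(1.368, abs=5e-4)


def test_nonpositive_inputs_rejected():
    for fn in (sphericity, mci):
        with pytest.raises(ValueError):
            fn(0.0, 1.0)
        with pytest.raises(ValueError):
            fn(1.0, -2.0)


@settings(deadline=None, max_examples=50)
@given(
    V=st.floats(min_value=1e-3, max_value=1e4),
    SA=st.floats(min_value=1e-3, max_value=1e4),
)
def test_mci_is_inverse_cube_of_sphericity(V, SA):
    assert mci(V, SA) * sphericity(V, SA) ** 3 == pytest.approx(1.0, abs=1e-12)


def test_sphericity_decreases_with_ellipsoid_aspect():
    # fixed volume, growing elongation: psi strictly decreasing (quadrature SA)
    psis = []
    for aspect in (1.0, 1.5, 2.5, 4.0):
        b = (1.0 / aspect) ** (1 / 3)  # keep a*b*c = 1
        a = aspect * b
        V = 4 / 3 * np.pi * a * b * b
        psis.append(sphericity(V, ellipsoid_surface_area(a, b, b)))
    assert all(x > y for x, y in zip(psis, psis[1:]))
    assert psis[0] == pytest.approx(1.0, rel=1e-10)


# ---------------------------------------------------------------------------
# whole-region quantification
# ---------------------------------------------------------------------------

def test_quantify_region_record_per_object(mixed_phantom):
    lv, gt = mixed_phantom
    df, qc = quantify_region(lv)
    assert len(df) == len(gt) == qc.n_kept
    merged = df.merge(gt, on="label", suffixes=("", "_gt"))
    exact = merged[merged["gt_method"] == "exact"]
    assert (np.abs(exact["volume_um3"] / exact["volume_um3_gt"] - 1) < 0.06).all()
    assert (np.abs(exact["surface_um2"] / exact["surface_um2_gt"] - 1) < 0.06).all()
    assert (merged["sphericity"] <= 1.02).all()
    assert (merged["mci"] >= 1 - 0.06).all()


def test_quantify_empty_volume_returns_empty_table():
    df, qc = quantify_region(LabelVolume(np.zeros((4, 4, 4), np.uint16), (1, 1, 1)))
    assert df.empty
    assert any("empty" in w for w in qc.warnings)


def test_scale_covariance_is_exact(sphere15):
    """Scaling the voxel spacing by s must scale V by s^3, SA by s^2 and the
    slice perimeter by s, leaving psi and MCI bit-unchanged."""
    s = 2.5
    V1 = volume_of(sphere15, (1, 1, 1))
    SA1 = surface_area_of(sphere15, (1, 1, 1))
    P1 = slice_perimeter_of(sphere15, (1, 1, 1))
    V2 = volume_of(sphere15, (s, s, s))
    SA2 = surface_area_of(sphere15, (s, s, s))
    P2 = slice_perimeter_of(sphere15, (s, s, s))
    assert V2 == pytest.approx(s**3 * V1, rel=1e-12)
    assert SA2 == pytest.approx(s**2 * SA1, rel=1e-12)
    assert P2 == pytest.approx(s * P1, rel=1e-12)
    assert sphericity(V2, SA2) == pytest.approx(sphericity(V1, SA1), rel=1e-12)
    assert mci(V2, SA2) == pytest.approx(mci(V1, SA1), rel=1e-12)


def test_sphericity_error_shrinks_along_radius_ladder():
    errs = [abs(1 - sphericity(volume_of(o, (1, 1, 1)),
                               surface_area_of(o, (1, 1, 1))))
            for o in (sphere_object(r) for r in (5, 10, 20, 40))]
    assert all(a > b for a, b in zip(errs, errs[1:]))


def test_volume_ranking_matches_analytic_ranking():
    from mitomorph.phantoms import PhantomSpec, generate_phantom_volume

    spec = PhantomSpec(shape_family="sphere", count=15, grid_shape=(40, 160, 160),
                       seed=21)
    lv, gt = generate_phantom_volume(spec)
    df, _ = quantify_region(lv)
    m = df.merge(gt, on="label", suffixes=("", "_gt"))
    rho = spearmanr(m["volume_um3"], m["volume_um3_gt"]).statistic
    assert rho == pytest.approx(1.0, abs=1e-12)
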