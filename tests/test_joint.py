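"""Whole-joint metrics: alignment, landmarks, angles, JSW, COM, loading."""

import numpy as np
import pytest

from qma.joint import (ContactCurve, LandmarkSet, align_to_reference,
                       com_vector, condyle_landmarks, contact_metrics,
                       direction_cosine_residual, joint_space_width,
                       margin_angles, split_compartments, surface_height_map,
                       twist_angle, virtual_loading)
from qma.phantom import PhantomSpec, make_joint_phantom
from qma.volumes import FEMUR, TIBIA, RigidTransform


# ---------------------------------------------------------------------------
# alignment and twist
# ---------------------------------------------------------------------------

def _box(shape=(21, 11, 41)):
    m = np.zeros(tuple(s + 4 for s in shape), bool)
    m[2:2 + shape[0], 2:2 + shape[1], 2:2 + shape[2]] = True
    return m


def test_axis_aligned_mask_yields_identity_pose():
    pose, aligned = align_to_reference(_box(), 0.1, "femur")
    assert np.max(np.abs(pose.euler_zyx_deg)) < 1e-6
    np.testing.assert_array_equal(aligned, _box())


def _rotated_ellipsoid(yaw, pitch, n=61):
    x = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    R = RigidTransform.from_euler_zyx(yaw, pitch, 0.0).rotation
    # inverse-rotate coordinates, then test canonical ellipsoid membership
    Xi = R[0, 0] * X + R[1, 0] * Y + R[2, 0] * Z
    Yi = R[0, 1] * X + R[1, 1] * Y + R[2, 1] * Z
    Zi = R[0, 2] * X + R[1, 2] * Y + R[2, 2] * Z
    a = n / 61.0
    return (Xi / (18 * a)) ** 2 + (Yi / (8 * a)) ** 2 + (Zi / (27 * a)) ** 2 <= 1.0


def test_known_rotation_recovered_within_half_degree():
    mask = _rotated_ellipsoid(yaw=5.0, pitch=3.0)
    pose, _ = align_to_reference(mask, 0.1, "femur")
    yaw, pitch, roll = pose.euler_zyx_deg
    assert abs(yaw - 5.0) < 0.5
    assert abs(pitch - 3.0) < 0.5
    assert abs(roll) < 0.5


def test_alignment_is_idempotent():
    mask = _rotated_ellipsoid(yaw=5.0, pitch=3.0, n=91)
    _, aligned = align_to_reference(mask, 0.1, "femur")
    pose2, _ = align_to_reference(aligned, 0.1, "femur")
    ang = np.degrees(np.arccos(np.clip((np.trace(pose2.rotation) - 1) / 2, -1, 1)))
    assert ang < 0.2


def test_spherical_mask_rejected_as_degenerate():
    n = 31
    x = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    ball = X ** 2 + Y ** 2 + Z ** 2 <= 12 ** 2
    with pytest.raises(ValueError, match="degenerate"):
        align_to_reference(ball, 0.1, "femur")


def test_twist_angle_identity_antisymmetry_and_wrap():
    t0 = RigidTransform.identity()
    t5 = RigidTransform.from_euler_zyx(5.0, 0, 0)
    assert twist_angle(t0, t0) == 0.0
    assert twist_angle(t5, t0) == pytest.approx(5.0)
    assert twist_angle(t0, t5) == pytest.approx(-5.0)
    t350 = RigidTransform.from_euler_zyx(-170.0, 0, 0)
    t170 = RigidTransform.from_euler_zyx(170.0, 0, 0)
    assert twist_angle(t350, t170) == pytest.approx(20.0)


def test_phantom_applied_yaw_recovered_as_twist(yawed_phantom):
    lab, truth = yawed_phantom
    pf, _ = align_to_reference(lab.mask(FEMUR), lab.spacing_mm, "femur")
    pt, _ = align_to_reference(lab.mask(TIBIA), lab.spacing_mm, "tibia")
    assert twist_angle(pf, pt) == pytest.approx(truth["tau"], abs=0.5)


# ---------------------------------------------------------------------------
# height maps and landmarks
# ---------------------------------------------------------------------------

def test_flat_slab_height_map_is_constant():
    m = np.zeros((10, 10, 20), bool)
    m[:, :, 5:12] = True
    hm = surface_height_map(m, 0.1, "proximal")
    np.testing.assert_allclose(hm, 11 * 0.1)
    hm_d = surface_height_map(m, 0.1, "distal")
    np.testing.assert_allclose(hm_d, 5 * 0.1)


def test_hemisphere_height_map_matches_analytic_cap():
    n, r = 41, 15
    x = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(x, x, np.arange(25), indexing="ij")
    dome = (X ** 2 + Y ** 2 + (Z - 0) ** 2 <= r ** 2) & (Z >= 0)
    hm = surface_height_map(dome, 1.0, "proximal")
    for i, j in ((20, 20), (25, 20), (20, 28), (12, 12)):
        d2 = x[i] ** 2 + x[j] ** 2
        if d2 <= (r - 1) ** 2:
            assert abs(hm[i, j] - np.sqrt(r ** 2 - d2)) <= 1.0


def test_unoccupied_columns_flagged_nan():
    m = np.zeros((6, 6, 6), bool)
    m[2:4, 2:4, 2:4] = True
    hm = surface_height_map(m, 1.0)
    assert np.isnan(hm[0, 0]) and np.isfinite(hm[2, 2])


def test_phantom_landmarks_within_one_voxel_of_truth(joint_record, joint_phantom):
    _, _, truth = joint_phantom
    _, extras = joint_record
    lms = extras["landmarks_femur"]
    s = 0.05
    for got, want in ((lms.lateral_min_mm, truth["landmark_lateral"]),
                      (lms.medial_min_mm, truth["landmark_medial"]),
                      (lms.notch_max_mm, truth["landmark_notch"])):
        assert np.all(np.abs(got - want) <= s + 1e-9)
    # interior ordering
    assert min(lms.lateral_min_mm[0], lms.medial_min_mm[0]) < lms.notch_max_mm[0] \
        < max(lms.lateral_min_mm[0], lms.medial_min_mm[0])


def test_osteophyte_bump_pulls_medial_landmark(osteophyte_sweep, joint_phantom):
    _, _, base_truth = joint_phantom
    _, lab, truth = osteophyte_sweep[-1]
    hm = surface_height_map(lab.mask(FEMUR), lab.spacing_mm, "distal")
    lms = condyle_landmarks(hm, lab.spacing_mm, lab.laterality)
    assert lms.medial_min_mm[2] < base_truth["landmark_medial"][2]
    assert np.all(np.abs(lms.medial_min_mm - truth["landmark_medial"])
                  <= lab.spacing_mm + 1e-9)


def test_single_bump_surface_has_no_notch():
    m = np.zeros((30, 10, 20), bool)
    x = np.arange(30) - 14.5
    X, Y, Z = np.meshgrid(x, np.arange(10), np.arange(20), indexing="ij")
    m |= X ** 2 + (Z - 15) ** 2 <= 8 ** 2
    hm = surface_height_map(m, 1.0, "distal")
    with pytest.raises(ValueError, match="notch not found"):
        condyle_landmarks(hm, 1.0)


# ---------------------------------------------------------------------------
# margin angles
# ---------------------------------------------------------------------------

def test_margin_angle_hand_trigonometry():
    lms = LandmarkSet(lateral_min_mm=np.array([-4.0, 0.0, 0.0]),
                      medial_min_mm=np.array([4.0, 0.0, 0.0]),
                      notch_max_mm=np.array([0.0, 0.0, 2.0]))
    sig_l, sig_m, rho = margin_angles(lms)
    assert sig_l == pytest.approx(np.degrees(np.arctan(4 / 2)))
    assert sig_l == pytest.approx(63.4349, abs=1e-3)
    assert rho == 0.0


def test_rho_sign_positive_when_medial_more_proximal():
    lms = LandmarkSet(lateral_min_mm=np.array([-4.0, 0.0, 0.0]),
                      medial_min_mm=np.array([4.0, 0.0, 0.7]),
                      notch_max_mm=np.array([0.0, 0.0, 2.0]))
    _, _, rho = margin_angles(lms)
    assert rho == pytest.approx(np.degrees(np.arctan2(0.7, 8.0)))
    assert rho > 0


def test_coincident_landmarks_rejected():
    p = np.zeros(3)
    with pytest.raises(ValueError):
        margin_angles(LandmarkSet(p, p, p))


def test_sigma_decreases_with_growing_medial_osteophyte(osteophyte_sweep):
    sigmas = []
    for _, lab, truth in osteophyte_sweep:
        hm = surface_height_map(lab.mask(FEMUR), lab.spacing_mm, "distal")
        lms = condyle_landmarks(hm, lab.spacing_mm, lab.laterality)
        _, sig_m, _ = margin_angles(lms)
        sigmas.append(sig_m)
        assert sig_m == pytest.approx(truth["sigma_fm"], abs=1.0)
    assert all(a > b for a, b in zip(sigmas, sigmas[1:]))


# ---------------------------------------------------------------------------
# compartments, JSW, COM
# ---------------------------------------------------------------------------

def test_compartment_split_is_a_partition(joint_phantom, joint_record):
    _, lab, _ = joint_phantom
    _, extras = joint_record
    lat, med = split_compartments(lab, extras["landmarks_femur"])
    assert np.all(lat ^ med)
    fem = lab.mask(FEMUR)
    n_lat, n_med = (fem & lat).sum(), (fem & med).sum()
    assert abs(n_lat - n_med) / fem.sum() < 0.01


def test_compartment_split_falls_back_to_com_with_warning(joint_phantom):
    _, lab, _ = joint_phantom
    with pytest.warns(UserWarning, match="centre-of-mass"):
        lat, med = split_compartments(lab, None)
    assert np.all(lat ^ med)


def test_jsw_recovers_constructed_gap(joint_record, joint_phantom):
    _, _, truth = joint_phantom
    rec, _ = joint_record
    assert rec.jsw_l_mm == pytest.approx(truth["jsw_l"], abs=0.05)
    assert rec.jsw_m_mm == pytest.approx(truth["jsw_m"], abs=0.05)


def test_jsw_translation_equivariance(joint_phantom):
    _, lab, _ = joint_phantom
    s = lab.spacing_mm
    femur, tibia = lab.mask(FEMUR), lab.mask(TIBIA)

    def jsw_of(fm):
        hm = surface_height_map(fm, s, "distal")
        lms = condyle_landmarks(hm, s, lab.laterality)
        return joint_space_width(fm, tibia, lms, s)

    base = jsw_of(femur)
    shifted = np.roll(femur, 4, axis=2)     # +4 voxels = +0.2 mm in z
    up = jsw_of(shifted)
    assert up[0] - base[0] == pytest.approx(0.2, abs=1e-9)
    assert up[1] - base[1] == pytest.approx(0.2, abs=1e-9)


def test_com_vector_axis_aligned_case():
    a = np.zeros((9, 9, 30), bool)
    b = np.zeros((9, 9, 30), bool)
    a[2:7, 2:7, 20:25] = True
    b[2:7, 2:7, 5:10] = True
    lam, al, be, ga, v = com_vector(a, b, 0.1)
    assert lam == pytest.approx(1.5)
    assert (al, be, ga) == (pytest.approx(90.0), pytest.approx(90.0),
                            pytest.approx(0.0))


def test_direction_cosine_identity_random_masks(rng):
    for _ in range(5):
        a = rng.random((12, 12, 12)) > 0.7
        b = rng.random((12, 12, 12)) > 0.7
        a[0, 0, 0] = b[-1, -1, -1] = True
        try:
            _, al, be, ga, _ = com_vector(a, b, 0.1)
        except ValueError:
            continue
        assert direction_cosine_residual(al, be, ga) < 1e-9


# ---------------------------------------------------------------------------
# virtual loading
# ---------------------------------------------------------------------------

def test_first_contact_step_matches_gap_without_cartilage():
    _, lab, truth = make_joint_phantom(
        PhantomSpec(cartilage_thickness_mm=(0.0, 0.0)))
    s = lab.spacing_mm
    curve = virtual_loading(lab.mask(FEMUR), lab.mask(TIBIA), s,
                            split_x_mm=lab.shape[0] / 2 * s, max_steps=40)
    chi_l, chi_m, _, _ = contact_metrics(curve)
    assert chi_l == pytest.approx(truth["joint_gap"], abs=s)
    assert chi_m == pytest.approx(truth["joint_gap"], abs=s)


def test_contact_area_monotone_for_sphere_on_plane(joint_record):
    _, extras = joint_record
    curve = extras["contact_curve"]
    assert np.all(np.diff(curve.contact_area_l_mm2) >= 0)
    assert np.all(np.diff(curve.contact_area_m_mm2) >= 0)


def test_contact_slope_matches_analytic_overlap(joint_record, joint_phantom):
    _, _, truth = joint_phantom
    rec, _ = joint_record
    assert rec.m_l_mm2_per_mm == pytest.approx(truth["m_l"], rel=0.10)
    assert rec.m_m_mm2_per_mm == pytest.approx(truth["m_m"], rel=0.10)
    assert rec.chi_l_mm == pytest.approx(truth["chi_l"], abs=0.05)
    assert rec.chi_m_mm == pytest.approx(truth["chi_m"], abs=0.05)


def test_intersecting_volumes_rejected():
    a = np.zeros((6, 6, 6), bool)
    a[2:5, 2:5, 2:5] = True
    with pytest.raises(ValueError, match="intersecting"):
        virtual_loading(a, a, 0.1, split_x_mm=0.3)


def test_contact_metrics_linear_curve_exact():
    d = np.arange(0, 41) * 0.05
    area = np.where(d >= 0.3, 50.0 * (d - 0.3), 0.0)
    curve = ContactCurve(d, area, area, 0.05)
    chi_l, chi_m, m_l, m_m = contact_metrics(curve)
    assert chi_l == pytest.approx(0.3)
    assert chi_m == pytest.approx(0.3)
    assert m_l == pytest.approx(50.0, rel=1e-9)
    assert m_m == pytest.approx(50.0, rel=1e-9)


def test_no_contact_flagged_missing_without_error():
    d = np.arange(0, 10) * 0.05
    zero = np.zeros_like(d)
    chi_l, chi_m, m_l, m_m = contact_metrics(ContactCurve(d, zero, zero, 0.05))
    assert np.isnan(chi_l) and np.isnan(m_m)
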