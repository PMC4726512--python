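"""Volume containers, I/O round-trips and pre-processing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qma.volumes import (LabelVolume, RigidTransform, ScalarVolume,
                         gaussian_kernel_1d, gaussian_smooth, read_volume,
                         resample_rigid, segment_threshold, write_volume)


# ---------------------------------------------------------------------------
# constrained Gauss filter
# ---------------------------------------------------------------------------

def analytic_kernel(sigma, support):
    d = np.arange(-support, support + 1, dtype=float)
    w = np.exp(-d ** 2 / (2 * sigma ** 2))
    return w / w.sum()


def test_impulse_response_matches_truncated_renormalised_gaussian():
    """The (sigma=1.2, s=1) impulse response equals the analytic separable
    3x3x3 kernel and sums to one."""
    vol = ScalarVolume(np.zeros((7, 7, 7)), 0.05)
    vol.data[3, 3, 3] = 1.0
    out = gaussian_smooth(vol, sigma=1.2, support=1)
    k = analytic_kernel(1.2, 1)
    expected = k[:, None, None] * k[None, :, None] * k[None, None, :]
    np.testing.assert_allclose(out.data[2:5, 2:5, 2:5], expected, atol=1e-14)
    assert abs(out.data.sum() - 1.0) < 1e-12
    assert np.all(out.data[:2] == 0)  # support truncation really is +-1 voxel


@given(sigma=st.floats(0.3, 5.0), support=st.integers(1, 4))
@settings(max_examples=30, derandomize=True, deadline=None)
def test_kernel_normalisation_for_any_parameters(sigma, support):
    assert abs(gaussian_kernel_1d(sigma, support).sum() - 1.0) < 1e-12


def test_constant_volume_preserved_by_filter():
    vol = ScalarVolume(np.full((6, 5, 8), 3.7), 0.05)
    out = gaussian_smooth(vol, 1.2, 1)
    np.testing.assert_allclose(out.data, 3.7, atol=1e-12)


def test_filter_support_larger_than_volume_rejected():
    vol = ScalarVolume(np.zeros((3, 10, 10)), 0.05)
    with pytest.raises(ValueError):
        gaussian_smooth(vol, 1.2, support=3)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("suffix,fmt,needs_spacing", [
    (".nii.gz", "nifti", False),
    (".mha", "metaimage", False),
    (".tif", "tiff_stack", True),
])
def test_label_roundtrip_bit_identical(tmp_path, rng, suffix, fmt, needs_spacing):
    labels = rng.integers(0, 5, size=(10, 12, 8)).astype(np.int16)
    lab = LabelVolume(labels, 0.018)
    path = write_volume(lab, tmp_path / f"lab{suffix}", format=fmt)
    back = read_volume(path, format=fmt, as_labels=True,
                       spacing_override_mm=0.018 if needs_spacing else None)
    np.testing.assert_array_equal(back.labels, labels)
    assert back.spacing_mm == pytest.approx(0.018)


@pytest.mark.parametrize("suffix,fmt,needs_spacing", [
    (".nii", "nifti", False),
    (".mha", "metaimage", False),
    (".tif", "tiff_stack", True),
])
def test_scalar_roundtrip_within_float32(tmp_path, rng, suffix, fmt, needs_spacing):
    data = rng.normal(size=(10, 10, 10)).astype(np.float32)
    vol = ScalarVolume(data, 0.018)
    path = write_volume(vol, tmp_path / f"vol{suffix}", format=fmt)
    back = read_volume(path, format=fmt,
                       spacing_override_mm=0.018 if needs_spacing else None)
    assert np.max(np.abs(back.data - data)) < 1e-6


def test_anisotropic_header_without_override_rejected(tmp_path):
    import nibabel as nib

    aff = np.diag([0.018, 0.018, 0.036, 1.0])
    nib.save(nib.Nifti1Image(np.zeros((5, 5, 5), np.float32), aff),
             str(tmp_path / "aniso.nii"))
    with pytest.raises(ValueError, match="anisotropic"):
        read_volume(tmp_path / "aniso.nii")
    # explicit override resolves it
    vol = read_volume(tmp_path / "aniso.nii", spacing_override_mm=0.018)
    assert vol.spacing_mm == 0.018


def test_missing_file_raises_io_error_with_path():
    with pytest.raises(IOError, match="nowhere.nii"):
        read_volume("nowhere.nii")


def test_tiff_without_spacing_override_rejected(tmp_path, rng):
    vol = ScalarVolume(rng.normal(size=(4, 4, 4)).astype(np.float32), 0.05)
    path = write_volume(vol, tmp_path / "v.tif")
    with pytest.raises(ValueError, match="spacing"):
        read_volume(path)


# ---------------------------------------------------------------------------
# threshold segmentation
# ---------------------------------------------------------------------------

def _flood_components(mask):
    """Independent 26-connectivity component sizes by BFS flood fill."""
    mask = mask.copy()
    sizes = []
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    while mask.any():
        seed = tuple(np.argwhere(mask)[0])
        stack, size = [seed], 0
        mask[seed] = False
        while stack:
            p = stack.pop()
            size += 1
            for o in offs:
                q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
                if all(0 <= q[i] < mask.shape[i] for i in range(3)) and mask[q]:
                    mask[q] = False
                    stack.append(q)
        sizes.append(size)
    return sorted(sizes)


def test_binary_mask_reproduced_at_half_threshold():
    data = np.zeros((8, 8, 8))
    data[2:5, 2:5, 2:5] = 1.0
    vol = ScalarVolume(data, 0.05)
    lab = segment_threshold(vol, 0.5, target_label=1)
    np.testing.assert_array_equal(lab.labels > 0, data > 0.5)


def test_small_components_removed_against_flood_fill_oracle(rng):
    data = np.zeros((20, 20, 20))
    data[2:7, 2:7, 2:6] = 1.0        # 100-voxel component (5*5*4)
    data[15, 15, 15:18] = 1.0        # 3-voxel component
    vol = ScalarVolume(data, 0.05)
    assert _flood_components(data > 0.5) == [3, 100]
    lab = segment_threshold(vol, 0.5, target_label=1, min_component_voxels=10)
    assert _flood_components(lab.labels > 0) == [100]


def test_threshold_above_maximum_warns_and_returns_background():
    vol = ScalarVolume(np.ones((5, 5, 5)), 0.05)
    with pytest.warns(UserWarning, match="empty"):
        lab = segment_threshold(vol, 2.0, target_label=1)
    assert not lab.labels.any()


# ---------------------------------------------------------------------------
# rigid transforms and resampling
# ---------------------------------------------------------------------------

@given(yaw=st.floats(-179.0, 179.0), pitch=st.floats(-89.0, 89.0),
       roll=st.floats(-179.0, 179.0))
@settings(max_examples=50, derandomize=True, deadline=None)
def test_euler_decomposition_roundtrips(yaw, pitch, roll):
    t = RigidTransform.from_euler_zyx(yaw, pitch, roll)
    t2 = RigidTransform.from_euler_zyx(*t.euler_zyx_deg)
    assert np.allclose(t.rotation, t2.rotation, atol=1e-9)


def test_non_orthonormal_rotation_rejected():
    with pytest.raises(ValueError):
        RigidTransform(np.eye(3) * 2.0)


def test_identity_resample_is_noop_bitwise(rng):
    labels = rng.integers(0, 5, size=(9, 9, 9)).astype(np.int16)
    lab = LabelVolume(labels, 0.05)
    out = resample_rigid(lab, RigidTransform.identity(), "nearest")
    np.testing.assert_array_equal(out.labels, labels)


def test_quarter_turn_swaps_box_extents():
    labels = np.zeros((31, 31, 11), dtype=np.int16)
    labels[5:26, 12:19, 2:9] = 1   # 21 x 7 box, centred
    lab = LabelVolume(labels, 0.1)
    c = np.array([15, 15, 5]) * 0.1
    rot = RigidTransform.from_euler_zyx(90.0, 0.0, 0.0)
    t = RigidTransform(rot.rotation, c - rot.rotation @ c)
    out = resample_rigid(lab, t, "nearest")
    occ = np.argwhere(out.labels > 0)
    ext = occ.max(axis=0) - occ.min(axis=0) + 1
    assert tuple(ext) == (7, 21, 7)


def test_bspline_rotation_roundtrip_rms_below_one_percent():
    """+5 then -5 degree yaw of a smooth blob returns close to the input."""
    n = 40
    x = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    data = np.exp(-(X ** 2 / 80 + Y ** 2 / 40 + Z ** 2 / 60)).astype(np.float64)
    vol = ScalarVolume(data, 0.05)
    c = np.full(3, (n - 1) / 2 * 0.05)

    def about_centre(yaw):
        r = RigidTransform.from_euler_zyx(yaw, 0, 0)
        return RigidTransform(r.rotation, c - r.rotation @ c)

    once = resample_rigid(vol, about_centre(5.0), "bspline3")
    back = resample_rigid(once, about_centre(-5.0), "bspline3")
    core = (slice(4, -4),) * 3
    rms = np.sqrt(np.mean((back.data[core] - data[core]) ** 2))
    assert rms < 0.01 * (data.max() - data.min())


def test_label_volume_refuses_interpolating_resample():
    lab = LabelVolume(np.zeros((5, 5, 5), np.int16), 0.05)
    with pytest.raises(ValueError, match="nearest"):
        resample_rigid(lab, RigidTransform.identity(), "trilinear")


def test_label_volume_validates_codes_and_laterality():
    with pytest.raises(ValueError, match="label codes"):
        LabelVolume(np.full((3, 3, 3), 9, np.int16), 0.05)
    with pytest.raises(ValueError, match="laterality"):
        LabelVolume(np.zeros((3, 3, 3), np.int16), 0.05, laterality="up")
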