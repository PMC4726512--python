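"""Volumetric containers, I/O and pre-processing.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(x, y, z)`` with

  - ``x``: medial–lateral axis,
  - ``y``: antero–posterior axis,
  - ``z``: distal → proximal (z increases toward the femoral shaft).

* Voxel spacing is isotropic and stored in mm.  Index ``i`` maps to the
  physical coordinate ``origin_mm + i * spacing_mm`` (voxel centres,
  0-based).

* Label codes: 0 background, 1 femur bone, 2 tibia bone, 3 femoral
  cartilage, 4 tibial cartilage.

* Laterality: for a ``right`` knee the lateral side occupies the low-``x``
  half of the volume; for a ``left`` knee the high-``x`` half.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial.transform import Rotation

log = logging.getLogger("qma")

#: segmentation label codes shared by every module
BACKGROUND = 0
FEMUR = 1
TIBIA = 2
FEMORAL_CARTILAGE = 3
TIBIAL_CARTILAGE = 4
LABEL_CODES = (BACKGROUND, FEMUR, TIBIA, FEMORAL_CARTILAGE, TIBIAL_CARTILAGE)

_FORMATS = ("nifti", "metaimage", "tiff_stack")


@dataclass
class ScalarVolume:
    """A 3D attenuation image on an isotropic grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Attenuation values; any real dtype.
    spacing_mm : float
        Isotropic voxel spacing in mm (> 0).
    origin_mm : ndarray, shape (3,)
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("data must be a 3D array with all dims >= 1")
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer segmentation on the same grid as its paired :class:`ScalarVolume`."""

    labels: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    laterality: str = "right"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be > 0")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")
        extra = set(np.unique(self.labels)) - set(LABEL_CODES)
        if extra:
            raise ValueError(f"unknown label codes {sorted(extra)}; map them via config")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of the union of the given label codes."""
        return np.isin(self.labels, codes)

    def lateral_half(self) -> np.ndarray:
        """Boolean mask of the lateral x-half of the grid."""
        nx = self.labels.shape[0]
        m = np.zeros(self.labels.shape, dtype=bool)
        if self.laterality == "right":
            m[: nx // 2] = True
        else:
            m[nx // 2 :] = True
        return m


@dataclass
class RigidTransform:
    """Rigid body transform ``x_out = R @ x_in + t`` in physical mm coordinates."""

    rotation: np.ndarray
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        R = self.rotation
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3))

    @classmethod
    def from_euler_zyx(cls, yaw_deg: float, pitch_deg: float, roll_deg: float,
                       translation_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from intrinsic Z-Y-X Euler angles (yaw about z first)."""
        R = Rotation.from_euler("ZYX", [yaw_deg, pitch_deg, roll_deg],
                                degrees=True).as_matrix()
        return cls(R, np.asarray(translation_mm, dtype=float))

    @property
    def euler_zyx_deg(self) -> np.ndarray:
        """(yaw, pitch, roll) in degrees, intrinsic Z-Y-X order."""
        return Rotation.from_matrix(self.rotation).as_euler("ZYX", degrees=True)

    @property
    def yaw_deg(self) -> float:
        return float(self.euler_zyx_deg[0])

    def inverse(self) -> "RigidTransform":
        RT = self.rotation.T
        return RigidTransform(RT, -RT @ self.translation_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation_mm + self.translation_mm)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    s = "".join(path.suffixes[-2:]).lower()
    if s.endswith((".nii", ".nii.gz")):
        return "nifti"
    if s.endswith((".mha", ".mhd")):
        return "metaimage"
    if s.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise ValueError(f"cannot infer volume format from {path.name}")


def read_volume(path, format: str | None = None, spacing_override_mm: float | None = None,
                as_labels: bool = False, laterality: str = "right"):
    """Read a volumetric image.

    Parameters
    ----------
    path : path-like
    format : {"nifti", "metaimage", "tiff_stack"}, optional
        Inferred from the file extension when omitted.
    spacing_override_mm : float, optional
        Required for formats without spacing metadata (TIFF) and to
        overrule anisotropic headers.
    as_labels : bool
        Return a :class:`LabelVolume` (integer data) instead of a
        :class:`ScalarVolume`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}")

    origin = np.zeros(3)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        spacing = _resolve_spacing(zooms, spacing_override_mm, path)
    elif fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        # sitk arrays come back (z, y, x); restore (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = _resolve_spacing(np.asarray(img.GetSpacing()), spacing_override_mm, path)
        origin = np.asarray(img.GetOrigin(), dtype=float)
    else:  # tiff_stack
        import tifffile

        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise IOError(f"TIFF stack {path} is not 3D")
        data = data.transpose(2, 1, 0)  # pages are z-slices
        if spacing_override_mm is None:
            raise ValueError(f"TIFF stack {path} carries no spacing; "
                             "supply spacing_override_mm via config")
        spacing = float(spacing_override_mm)

    log.info("read %s [%s]: shape=%s spacing=%.6g mm", path.name, fmt, data.shape, spacing)
    if as_labels:
        return LabelVolume(data.astype(np.int16), spacing, origin, laterality)
    return ScalarVolume(data.astype(np.float32, copy=False), spacing, origin)


def _resolve_spacing(zooms: np.ndarray, override: float | None, path: Path) -> float:
    if override is not None:
        return float(override)
    if np.any(zooms <= 0):
        raise ValueError(f"{path}: missing voxel spacing and no override configured")
    if not np.allclose(zooms, zooms[0], rtol=1e-6):
        raise ValueError(f"{path}: anisotropic spacing {tuple(zooms)}; "
                         "supply an isotropic override or resample upstream")
    return float(zooms[0])


def write_volume(vol, path, format: str | None = None):
    """Write a :class:`ScalarVolume` or :class:`LabelVolume` to disk.

    Integer labels round-trip bit-identically; scalar data is written as
    32-bit float.  Returns the path written.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}")
    is_labels = isinstance(vol, LabelVolume)
    data = vol.labels.astype(np.int16) if is_labels else vol.data.astype(np.float32)
    spacing = vol.spacing_mm

    if fmt == "nifti":
        import nibabel as nib

        aff = np.diag([spacing, spacing, spacing, 1.0])
        aff[:3, 3] = vol.origin_mm
        nib.save(nib.Nifti1Image(data, aff), str(path))
    elif fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing((spacing,) * 3)
        img.SetOrigin(tuple(np.asarray(vol.origin_mm, dtype=float)))
        sitk.WriteImage(img, str(path))
    else:
        import tifffile

        tifffile.imwrite(str(path), np.ascontiguousarray(data.transpose(2, 1, 0)))
    log.info("wrote %s [%s]: shape=%s spacing=%.6g mm", path.name, fmt, data.shape, spacing)
    return path


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def gaussian_kernel_1d(sigma: float, support: int) -> np.ndarray:
    """Gaussian kernel truncated at ±``support`` voxels and renormalised to sum 1.

    This is the constrained Gauss filter parameterisation ``(sigma, s)``
    used by scanner-vendor pipelines: a small finite kernel rather than a
    quasi-infinite one.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if support < 1:
        raise ValueError("support must be >= 1")
    d = np.arange(-support, support + 1, dtype=float)
    w = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return w / w.sum()


def gaussian_smooth(vol: ScalarVolume, sigma: float = 1.2, support: int = 1) -> ScalarVolume:
    """Apply the constrained (truncated, renormalised) separable Gauss filter."""
    if support >= min(vol.shape):
        raise ValueError("support must be smaller than the smallest dimension")
    k = gaussian_kernel_1d(sigma, support)
    out = vol.data.astype(np.float64)
    for axis in range(3):
        out = ndi.convolve1d(out, k, axis=axis, mode="nearest")
    log.info("gaussian_smooth: shape=%s sigma=%.3g support=%d", vol.shape, sigma, support)
    return ScalarVolume(out, vol.spacing_mm, vol.origin_mm)


def segment_threshold(vol: ScalarVolume, threshold: float, target_label: int = FEMUR,
                      min_component_voxels: int = 0, laterality: str = "right") -> LabelVolume:
    """Global threshold segmentation with small-component removal.

    Voxels ``>= threshold`` receive ``target_label``; 26-connected
    components smaller than ``min_component_voxels`` are discarded.
    """
    if target_label not in LABEL_CODES or target_label == BACKGROUND:
        raise ValueError(f"target_label must be one of {LABEL_CODES[1:]}")
    mask = vol.data >= threshold
    if min_component_voxels > 1 and mask.any():
        structure = np.ones((3, 3, 3), dtype=bool)
        lab, n = ndi.label(mask, structure=structure)
        counts = np.bincount(lab.ravel())
        keep = counts >= min_component_voxels
        keep[0] = False
        mask = keep[lab]
    if not mask.any():
        warnings.warn("segment_threshold produced an empty segmentation", stacklevel=2)
    labels = np.where(mask, np.int16(target_label), np.int16(BACKGROUND))
    log.info("segment_threshold: thr=%.6g label=%d kept %d voxels",
             threshold, target_label, int(mask.sum()))
    return LabelVolume(labels, vol.spacing_mm, vol.origin_mm, laterality)


_ORDER = {"nearest": 0, "trilinear": 1, "bspline3": 3}


def resample_rigid(vol, transform: RigidTransform, interpolation: str = "trilinear"):
    """Resample a volume under a rigid transform, output on the input grid.

    The transform maps input physical coordinates to output physical
    coordinates; out-of-field voxels are set to 0 / background.  Label
    volumes must use nearest-neighbour interpolation.
    """
    if interpolation not in _ORDER:
        raise ValueError(f"interpolation must be one of {sorted(_ORDER)}")
    is_labels = isinstance(vol, LabelVolume)
    if is_labels and interpolation != "nearest":
        raise ValueError("label volumes must be resampled with nearest interpolation")
    data = vol.labels if is_labels else vol.data
    order = _ORDER[interpolation]

    if np.allclose(transform.rotation, np.eye(3), atol=1e-15) and \
       np.allclose(transform.translation_mm, 0.0, atol=1e-15):
        out = data.copy()
    else:
        s = vol.spacing_mm
        RT = transform.rotation.T
        # i_in = R^T i_out + (R^T (org - t) - org) / s   (voxel-index form)
        offset = (RT @ (vol.origin_mm - transform.translation_mm) - vol.origin_mm) / s
        out = ndi.affine_transform(data.astype(np.float64) if order else data,
                                   RT, offset=offset, order=order,
                                   mode="constant", cval=0.0, prefilter=(order == 3))
        if not order:
            out = out.astype(data.dtype)
        elif not is_labels:
            out = out.astype(np.float32)
    log.info("resample_rigid: %s interpolation, yaw=%.3f deg",
             interpolation, transform.yaw_deg)
    if is_labels:
        return LabelVolume(out.astype(vol.labels.dtype), vol.spacing_mm,
                           vol.origin_mm, vol.laterality)
    return ScalarVolume(out, vol.spacing_mm, vol.origin_mm)
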