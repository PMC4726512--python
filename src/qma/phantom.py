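"""Synthetic joint phantoms with analytic ground truth.

The study-scale inputs (contrast-enhanced microCT scans of rabbit knees)
are not distributable, so every metric in the package is validated
against phantoms whose true values are known in closed form or by
exhaustive voxel counting — never computed by the modules under test.

The joint phantom emulates the anatomy the whole-joint metrics assume:
a femur made of two spherical condyles joined by a proximal bridge (the
gap between them forming the intercondylar notch) and a long shaft; a
tibia made of a flat plateau with an optional eminence ridge and a long
shaft; cartilage shells of stated thickness on both articular surfaces;
a vertical bone-to-bone joint gap; and an optional marginal osteophyte
bump (a hemispherical bony outgrowth at the condylar margin, displacing
the condylar landmark distally so the margin angle sigma decreases with
bump size).

Default geometry (mm): condyle radius 1.5, condyle offset ±2.0 from the
midline, joint gap 1.0, cartilage 0.3 per surface, voxel spacing 0.05
(coarser than the study's 18 um so that a full phantom builds in
seconds while every structure stays >= 6 voxels across).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .volumes import (BACKGROUND, FEMORAL_CARTILAGE, FEMUR, TIBIA,
                      TIBIAL_CARTILAGE, LabelVolume, ScalarVolume)

__all__ = [
    "PhantomSpec", "PhantomTruth", "make_plate", "make_sphere",
    "make_trabecular_block", "make_joint_phantom", "make_repeated_measures",
    "RepeatedMeasuresTable",
]


@dataclass
class PhantomTruth:
    """Analytic / exhaustively-counted ground truth values with units."""

    values: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)

    def set(self, name: str, value, unit: str = "-") -> None:
        self.values[name] = value
        self.units[name] = unit

    def __getitem__(self, name):
        return self.values[name]

    def manifest(self) -> dict:
        return {k: {"value": (v.tolist() if isinstance(v, np.ndarray) else v),
                    "unit": self.units[k]} for k, v in self.values.items()}


@dataclass
class OsteophyteBump:
    """Marginal hemispherical bump: compartment, radius, centre offsets."""

    compartment: str = "medial"          # {"medial", "lateral"}
    radius_mm: float = 0.6
    peripheral_offset_mm: float = 0.3    # outward shift of the centre from the condyle centre x
    distal_offset_mm: float = 0.2        # bump centre height above the condylar minimum


@dataclass
class TrabecularSpec:
    volume_fraction_target: float = 0.45
    correlation_length_mm: tuple = (0.15, 0.15, 0.15)
    shape_vox: tuple = (64, 64, 64)
    seed: int = 0


@dataclass
class PhantomSpec:
    """Geometry of the two-bone joint phantom (all lengths in mm)."""

    spacing_mm: float = 0.05
    condyle_radius_mm: tuple = (1.5, 1.5)        # (lateral, medial)
    condyle_offset_mm: float = 2.0               # |x| of condyle centres from midline
    notch_depth_mm: float = 1.5                  # bridge underside above the condylar minima
    plateau_halfwidth_mm: tuple = (4.0, 2.5)     # (x, y)
    plateau_thickness_mm: float = 1.5
    eminence_height_mm: float = 0.6              # 0 disables the ridge
    eminence_halfwidth_mm: float = 0.3
    joint_gap_mm: float = 1.0
    cartilage_thickness_mm: tuple = (0.3, 0.3)   # (femoral, tibial)
    shaft_length_mm: float = 6.0                 # femoral shaft above the bridge
    tibial_shaft_length_mm: float = 8.0
    femur_yaw_deg: float = 0.0
    osteophyte_bump: OsteophyteBump | None = None
    trabecular: TrabecularSpec | None = None
    noise_sd: float = 0.0
    laterality: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spacing_mm", "condyle_offset_mm", "notch_depth_mm",
                     "plateau_thickness_mm", "joint_gap_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if min(self.condyle_radius_mm) <= 0:
            raise ValueError("condyle radii must be > 0")


# ---------------------------------------------------------------------------
# simple primitives
# ---------------------------------------------------------------------------

def make_plate(thickness_vox: int, lateral_extent_vox: int, spacing_mm: float,
               label: int = FEMORAL_CARTILAGE):
    """Axis-aligned solid slab spanning the full lateral extent of its grid.

    The slab fills x and y completely so the thickness transform sees an
    effectively infinite plate; two empty voxel layers pad z.
    """
    if thickness_vox < 2:
        raise ValueError("thickness must be >= 2 voxels")
    if lateral_extent_vox < thickness_vox:
        raise ValueError("lateral extent must be >= thickness")
    n = lateral_extent_vox
    labels = np.zeros((n, n, thickness_vox + 4), dtype=np.int16)
    labels[:, :, 2:2 + thickness_vox] = label
    truth = PhantomTruth()
    t_mm = thickness_vox * spacing_mm
    a = n * spacing_mm
    truth.set("thickness", t_mm, "mm")
    truth.set("volume", thickness_vox * n * n * spacing_mm ** 3, "mm^3")
    truth.set("surface", 2 * (a * a + a * t_mm + t_mm * a), "mm^2")
    truth.set("n_voxels", int(thickness_vox * n * n), "voxels")
    return LabelVolume(labels, spacing_mm), truth


def make_sphere(radius_mm: float, spacing_mm: float, label: int = FEMORAL_CARTILAGE):
    """Voxelised solid ball with closed-form truth values."""
    r_vox = radius_mm / spacing_mm
    if r_vox < 4:
        raise ValueError("radius must be >= 4 voxels for acceptable discretisation")
    n = int(np.ceil(r_vox)) + 3
    x = (np.arange(2 * n + 1) - n) * spacing_mm
    R2 = (x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2)
    labels = np.where(R2 <= radius_mm ** 2, np.int16(label), np.int16(BACKGROUND))
    truth = PhantomTruth()
    truth.set("thickness", 2 * radius_mm, "mm")
    truth.set("volume", 4.0 / 3.0 * np.pi * radius_mm ** 3, "mm^3")
    truth.set("surface", 4.0 * np.pi * radius_mm ** 2, "mm^2")
    truth.set("euler_characteristic", 1, "-")
    truth.set("n_voxels", int((R2 <= radius_mm ** 2).sum()), "voxels")
    return LabelVolume(labels, spacing_mm), truth


def make_trabecular_block(spec: TrabecularSpec | None = None,
                          spacing_mm: float = 0.05):
    """Thresholded smoothed Gaussian random field with exact volume fraction.

    The threshold is taken at the order statistic matching the target
    volume fraction, so the realised voxel-count BV/TV equals the target
    to within one voxel in N.  Anisotropy ground truth is the ordering of
    the per-axis correlation lengths (no closed form exists for the
    thickness of a random field, so Tb.Th/Tb.Sp carry no truth values).
    """
    spec = spec or TrabecularSpec()
    vf = spec.volume_fraction_target
    if not 0.0 < vf < 1.0:
        raise ValueError("volume_fraction_target must be in (0, 1)")
    corr_vox = np.asarray(spec.correlation_length_mm) / spacing_mm
    if np.any(corr_vox < 2):
        raise ValueError("correlation lengths must be >= 2 voxels")
    rng = np.random.default_rng(spec.seed)
    fld = rng.standard_normal(spec.shape_vox)
    fld = ndi.gaussian_filter(fld, sigma=corr_vox, mode="wrap")
    k = int(round(vf * fld.size))
    if k < 1 or k >= fld.size:
        raise ValueError("volume fraction unattainable at this grid size")
    thr = np.partition(fld.ravel(), fld.size - k)[fld.size - k]
    mask = fld >= thr
    realized = mask.sum() / mask.size

    truth = PhantomTruth()
    truth.set("bv_tv", 100.0 * realized, "%")
    cl = np.asarray(spec.correlation_length_mm)
    if np.allclose(cl, cl[0]):
        truth.set("anisotropy", "isotropic", "-")
    else:
        truth.set("anisotropy", "xyz"[int(np.argmax(cl))], "-")
        truth.set("anisotropy_axis", np.eye(3)[int(np.argmax(cl))], "-")
    truth.set("n_voxels", int(mask.sum()), "voxels")
    labels = np.where(mask, np.int16(TIBIA), np.int16(BACKGROUND))
    return LabelVolume(labels, spacing_mm), truth


# ---------------------------------------------------------------------------
# articulated joint phantom
# ---------------------------------------------------------------------------

# grid coordinates are spacing multiples accumulated in floating point; a
# small tolerance keeps nominally symmetric solids symmetric on the grid
_EPS = 1e-9


def _sphere_mask(X, Y, Z, c, r):
    return (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r ** 2 + _EPS


def _box_mask(X, Y, Z, xr, yr, zr):
    return ((X >= xr[0] - _EPS) & (X <= xr[1] + _EPS)
            & (Y >= yr[0] - _EPS) & (Y <= yr[1] + _EPS)
            & (Z >= zr[0] - _EPS) & (Z <= zr[1] + _EPS))


def make_joint_phantom(spec: PhantomSpec | None = None):
    """Two-bone articulated joint phantom.

    Returns ``(ScalarVolume, LabelVolume, PhantomTruth)``.  The scalar
    volume is a noisy rendering of the labels (bone 1.0, cartilage 0.5)
    for threshold-segmentation and filtering exercises.
    """
    spec = spec or PhantomSpec()
    s = spec.spacing_mm
    r_lat, r_med = spec.condyle_radius_mm
    cart_f, cart_t = spec.cartilage_thickness_mm
    g = spec.joint_gap_mm
    margin = 0.3

    # laterality: right knee -> lateral on the low-x side
    sgn_med = +1.0 if spec.laterality == "right" else -1.0

    px, py = spec.plateau_halfwidth_mm
    half_x = max(px, spec.condyle_offset_mm + max(r_lat, r_med) + 1.2) + margin
    half_y = max(py, max(r_lat, r_med)) + margin

    # z layout (bottom-up), all in volume coordinates (mm from voxel 0)
    z_t_shaft0 = margin
    z_plate0 = z_t_shaft0 + spec.tibial_shaft_length_mm
    z_plate1 = z_plate0 + spec.plateau_thickness_mm        # plateau top
    z_min = z_plate1 + g                                   # condylar minima
    z_notch = z_min + spec.notch_depth_mm                  # bridge underside
    r_max = max(r_lat, r_med)
    z_c = z_min + r_max                                    # condyle centre plane
    z_bridge1 = z_c + r_max
    z_top = z_bridge1 + spec.shaft_length_mm + margin

    nx = int(np.ceil(2 * half_x / s)) + 1
    ny = int(np.ceil(2 * half_y / s)) + 1
    nz = int(np.ceil(z_top / s)) + 1
    cx = (nx - 1) / 2.0 * s
    cy = (ny - 1) / 2.0 * s

    X = (np.arange(nx) * s - cx)[:, None, None]
    Y = (np.arange(ny) * s - cy)[None, :, None]
    Z = (np.arange(nz) * s)[None, None, :]

    # femur solids, optionally yawed about the vertical axis through (0, 0)
    yaw = np.deg2rad(spec.femur_yaw_deg)
    if yaw:
        Xf = np.cos(yaw) * X + np.sin(yaw) * Y
        Yf = -np.sin(yaw) * X + np.cos(yaw) * Y
    else:
        Xf, Yf = X, Y

    c_lat = np.array([-sgn_med * spec.condyle_offset_mm, 0.0, z_min + r_lat])
    c_med = np.array([sgn_med * spec.condyle_offset_mm, 0.0, z_min + r_med])
    bridge_hx = spec.condyle_offset_mm + r_max
    bridge_hy = r_max + 0.1
    femur = (_sphere_mask(Xf, Yf, Z, c_lat, r_lat)
             | _sphere_mask(Xf, Yf, Z, c_med, r_med)
             | _box_mask(Xf, Yf, Z, (-bridge_hx, bridge_hx), (-bridge_hy, bridge_hy),
                         (z_notch, z_bridge1))
             | _box_mask(Xf, Yf, Z, (-1.0, 1.0), (-1.0, 1.0),
                         (z_bridge1, z_bridge1 + spec.shaft_length_mm)))

    fem_cart = np.zeros_like(femur)
    if cart_f > 0:
        for c, r in ((c_lat, r_lat), (c_med, r_med)):
            shell = (_sphere_mask(Xf, Yf, Z, c, r + cart_f)
                     & ~_sphere_mask(Xf, Yf, Z, c, r) & (Z < c[2]))
            fem_cart |= shell

    bump = spec.osteophyte_bump
    bump_min_z = None
    if bump is not None:
        sgn_b = sgn_med if bump.compartment == "medial" else -sgn_med
        r_cond = r_med if bump.compartment == "medial" else r_lat
        c_b = np.array([sgn_b * (spec.condyle_offset_mm + bump.peripheral_offset_mm),
                        0.0, z_min + bump.distal_offset_mm])
        femur |= _sphere_mask(Xf, Yf, Z, c_b, bump.radius_mm)
        bump_min_z = c_b[2] - bump.radius_mm

    # tibia
    tibia = (_box_mask(X, Y, Z, (-px, px), (-py, py), (z_plate0, z_plate1))
             | _box_mask(X, Y, Z, (-1.25, 1.25), (-1.25, 1.25),
                         (z_t_shaft0, z_plate0)))
    if spec.eminence_height_mm > 0:
        ew = spec.eminence_halfwidth_mm
        tibia |= _box_mask(X, Y, Z, (-ew, ew), (-py, py),
                           (z_plate1, z_plate1 + spec.eminence_height_mm))
    tib_cart = np.zeros_like(tibia)
    if cart_t > 0:
        tib_cart = _box_mask(X, Y, Z, (-px, px), (-py, py),
                             (z_plate1, z_plate1 + cart_t)) & ~tibia

    if np.any(femur & tibia):
        raise ValueError("femur and tibia solids overlap; enlarge joint_gap_mm")

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    labels[tib_cart] = TIBIAL_CARTILAGE
    labels[fem_cart] = FEMORAL_CARTILAGE
    labels[tibia] = TIBIA
    labels[femur] = FEMUR

    rng = np.random.default_rng(spec.seed)
    scalar = np.zeros(labels.shape, dtype=np.float32)
    scalar[(labels == FEMUR) | (labels == TIBIA)] = 1.0
    scalar[(labels == FEMORAL_CARTILAGE) | (labels == TIBIAL_CARTILAGE)] = 0.5
    if spec.noise_sd > 0:
        scalar = scalar + rng.normal(0.0, spec.noise_sd, labels.shape).astype(np.float32)

    truth = _joint_truth(spec, sgn_med, cx, cy, z_plate0, z_plate1, z_min,
                         z_notch, z_c, z_bridge1, bump_min_z)
    vol = ScalarVolume(scalar, s)
    lab = LabelVolume(labels, s, laterality=spec.laterality)
    return vol, lab, truth


def _joint_truth(spec, sgn_med, cx, cy, z_plate0, z_plate1, z_min, z_notch,
                 z_c, z_bridge1, bump_min_z):
    """Closed-form ground truth for the joint phantom (volume coordinates)."""
    t = PhantomTruth()
    s = spec.spacing_mm
    r_lat, r_med = spec.condyle_radius_mm
    cart_f, cart_t = spec.cartilage_thickness_mm
    g = spec.joint_gap_mm
    off = spec.condyle_offset_mm
    bump = spec.osteophyte_bump

    x_lat = cx - sgn_med * off
    x_med = cx + sgn_med * off
    lm_lat = np.array([x_lat, cy, z_min])
    lm_med = np.array([x_med, cy, z_min])
    if bump is not None and bump_min_z is not None and bump_min_z < z_min:
        sgn_b = sgn_med if bump.compartment == "medial" else -sgn_med
        x_b = cx + sgn_b * (off + bump.peripheral_offset_mm)
        if bump.compartment == "medial":
            lm_med = np.array([x_b, cy, bump_min_z])
        else:
            lm_lat = np.array([x_b, cy, bump_min_z])
    t.set("landmark_lateral", lm_lat, "mm")
    t.set("landmark_medial", lm_med, "mm")
    t.set("landmark_notch", np.array([cx, cy, z_notch]), "mm")

    def chord(lm):
        return float(np.degrees(np.arctan2(abs(lm[0] - cx), z_notch - lm[2])))

    t.set("sigma_fl", chord(lm_lat), "deg")
    t.set("sigma_fm", chord(lm_med), "deg")
    rho = np.degrees(np.arctan2(lm_med[2] - lm_lat[2], abs(lm_med[0] - lm_lat[0])))
    t.set("rho", float(rho), "deg")

    # tibial margin angles: flat plateau minima (centroid of each half
    # outside the eminence strip) against the eminence maximum
    if spec.eminence_height_mm > 0:
        px = spec.plateau_halfwidth_mm[0]
        ew = spec.eminence_halfwidth_mm
        x_centroid = (ew + px) / 2.0
        sig_t = float(np.degrees(np.arctan2(x_centroid, spec.eminence_height_mm)))
        t.set("sigma_tl", sig_t, "deg")
        t.set("sigma_tm", sig_t, "deg")

    t.set("jsw_l", g, "mm")
    jsw_m = g
    if bump is not None and bump_min_z is not None and bump.compartment == "medial":
        jsw_m = bump_min_z - z_plate1
    t.set("jsw_m", jsw_m, "mm")
    chi_l = g - cart_f - cart_t
    chi_m = chi_l
    if bump is not None and bump_min_z is not None and bump.compartment == "medial":
        chi_m = bump_min_z - (z_plate1 + cart_t)   # bump is bare bone
    t.set("chi_l", chi_l, "mm")
    t.set("chi_m", chi_m, "mm")
    t.set("tau", spec.femur_yaw_deg, "deg")
    t.set("cartilage_thickness_femoral", cart_f, "mm")
    t.set("cartilage_thickness_tibial", cart_t, "mm")
    t.set("joint_gap", g, "mm")

    # analytic slope of the projected contact-area curve over the default
    # 10-step fit window: both compartments are sphere-on-plane contacts
    # with outer (cartilage) radius R, A(d) = pi (2 R d - d^2)
    steps = np.arange(0, 11) * s
    for side, r in (("l", r_lat), ("m", r_med)):
        if bump is not None and side == ("m" if bump.compartment == "medial" else "l"):
            continue  # bump contact is not a clean sphere-on-plane
        R = r + cart_f
        d = steps  # penetration beyond first contact
        A = np.pi * (2 * R * d - d ** 2)
        slope = np.polyfit(d, A, 1)[0]
        t.set(f"m_{side}", float(slope), "mm^2/mm")

    # centre-of-mass vector (bone only) from composite solids; the bridge
    # overlaps each condyle in exactly its upper hemisphere by construction
    if spec.femur_yaw_deg == 0.0 and bump is None:
        r_max = max(r_lat, r_med)
        parts = []  # (volume, centroid_z)
        for r in (r_lat, r_med):
            parts.append((4.0 / 3.0 * np.pi * r ** 3, z_min + r))
            parts.append((-2.0 / 3.0 * np.pi * r ** 3, z_c + 3.0 * r / 8.0))
        bx = off + r_max
        by = r_max + 0.1
        parts.append((2 * bx * 2 * by * (z_bridge1 - z_notch),
                      (z_notch + z_bridge1) / 2.0))
        parts.append((2.0 * 2.0 * spec.shaft_length_mm,
                      z_bridge1 + spec.shaft_length_mm / 2.0))
        vf = sum(v for v, _ in parts)
        zf = sum(v * z for v, z in parts) / vf

        px, py = spec.plateau_halfwidth_mm
        tparts = [(2 * px * 2 * py * spec.plateau_thickness_mm,
                   (z_plate0 + z_plate1) / 2.0),
                  (2.5 * 2.5 * spec.tibial_shaft_length_mm,
                   z_plate0 - spec.tibial_shaft_length_mm / 2.0)]
        if spec.eminence_height_mm > 0:
            tparts.append((2 * spec.eminence_halfwidth_mm * 2 * py
                           * spec.eminence_height_mm,
                           z_plate1 + spec.eminence_height_mm / 2.0))
        vt = sum(v for v, _ in tparts)
        zt = sum(v * z for v, z in tparts) / vt

        v = np.array([0.0, 0.0, zf - zt])
        lam = float(np.linalg.norm(v))
        t.set("com_vector", v, "mm")
        t.set("lambda", lam, "mm")
        t.set("alpha", 90.0, "deg")
        t.set("beta", 90.0, "deg")
        t.set("gamma", 0.0 if v[2] >= 0 else 180.0, "deg")
    return t


# ---------------------------------------------------------------------------
# repeated-measures tables
# ---------------------------------------------------------------------------

@dataclass
class RepeatedMeasuresTable:
    """Subjects x repeats measurement matrix (no missing cells)."""

    values: np.ndarray
    subject_ids: list
    repeat_labels: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (subjects x repeats)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need >= 2 subjects and >= 2 repeats")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing cells are not allowed; drop rows upstream")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.values.shape[1]


def make_repeated_measures(n_subjects: int, n_repeats: int, between_sd: float,
                           within_sd: float, mean: float = 0.0,
                           seed: int = 0) -> RepeatedMeasuresTable:
    """x_ij = mean + b_i + e_ij, b ~ N(0, between_sd^2), e ~ N(0, within_sd^2).

    The expected intraclass correlation is
    ``between_sd^2 / (between_sd^2 + within_sd^2)``.
    """
    if n_subjects < 2 or n_repeats < 2:
        raise ValueError("need >= 2 subjects and >= 2 repeats")
    if between_sd < 0 or within_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, between_sd, size=(n_subjects, 1))
    e = rng.normal(0.0, within_sd, size=(n_subjects, n_repeats))
    values = mean + b + e
    return RepeatedMeasuresTable(values,
                                 [f"S{i + 1}" for i in range(n_subjects)],
                                 [f"HEX{j + 1}" for j in range(n_repeats)])
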