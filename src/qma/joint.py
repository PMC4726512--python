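"""Whole-joint in-situ morphometry of an articulated two-bone joint.

Metrics (all computed in the tibial reference frame, z vertical):

* ``sigma`` [deg] — margin angles: per compartment, the coronal-plane
  (XZ) angle between the vertical axis and the chord from the
  intercondylar notch maximum (or tibial eminence) to the compartment's
  surface minimum.  Marginal osteophytes displace the minima distally
  and peripherally, reducing (sharpening) sigma.
* ``rho`` [deg] — inclination of the line joining the two condylar
  minima; positive when the medial minimum is more proximal.
* ``JSW`` [mm] — joint space width per compartment: vertical distance
  from the condylar landmark to the first tibial bone voxel below it.
* ``lambda, alpha, beta, gamma`` — length and direction angles of the
  femur-to-tibia centre-of-mass vector.
* ``tau`` [deg] — twist: difference in yaw between the femoral and
  tibial canonical orientations (ZYX Euler convention, femur minus
  tibia, wrapped to (-180, 180]).
* ``chi`` [mm], ``m`` [mm^2/mm] — virtual loading: the femur (bone +
  cartilage) is translated down in voxel steps; chi is the displacement
  at first contact per compartment and m the initial slope of contact
  area against displacement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volumes import (FEMORAL_CARTILAGE, FEMUR, TIBIA, TIBIAL_CARTILAGE,
                      LabelVolume, RigidTransform, resample_rigid)

log = logging.getLogger("qma")

__all__ = [
    "JointMetricsRecord", "LandmarkSet", "ContactCurve",
    "align_to_reference", "split_compartments", "surface_height_map",
    "condyle_landmarks", "margin_angles", "joint_space_width", "com_vector",
    "twist_angle", "virtual_loading", "contact_metrics", "compute_joint_metrics",
]


@dataclass
class JointMetricsRecord:
    """Every whole-joint output; NaN marks a metric that could not be formed."""

    sigma_fl_deg: float = np.nan
    sigma_fm_deg: float = np.nan
    sigma_tl_deg: float = np.nan
    sigma_tm_deg: float = np.nan
    rho_deg: float = np.nan
    jsw_l_mm: float = np.nan
    jsw_m_mm: float = np.nan
    lambda_mm: float = np.nan
    alpha_deg: float = np.nan
    beta_deg: float = np.nan
    gamma_deg: float = np.nan
    tau_deg: float = np.nan
    chi_l_mm: float = np.nan
    chi_m_mm: float = np.nan
    m_l_mm2_per_mm: float = np.nan
    m_m_mm2_per_mm: float = np.nan

    def as_dict(self) -> dict:
        return {
            "sigma_F.L [deg]": self.sigma_fl_deg,
            "sigma_F.M [deg]": self.sigma_fm_deg,
            "sigma_T.L [deg]": self.sigma_tl_deg,
            "sigma_T.M [deg]": self.sigma_tm_deg,
            "rho [deg]": self.rho_deg,
            "JSW_L [mm]": self.jsw_l_mm,
            "JSW_M [mm]": self.jsw_m_mm,
            "lambda [mm]": self.lambda_mm,
            "alpha [deg]": self.alpha_deg,
            "beta [deg]": self.beta_deg,
            "gamma [deg]": self.gamma_deg,
            "tau [deg]": self.tau_deg,
            "chi_L [mm]": self.chi_l_mm,
            "chi_M [mm]": self.chi_m_mm,
            "chi_L [um]": self.chi_l_mm * 1000.0,
            "chi_M [um]": self.chi_m_mm * 1000.0,
            "m_L [mm^2/mm]": self.m_l_mm2_per_mm,
            "m_M [mm^2/mm]": self.m_m_mm2_per_mm,
        }


@dataclass
class LandmarkSet:
    """Surface landmarks in volume mm coordinates."""

    lateral_min_mm: np.ndarray
    medial_min_mm: np.ndarray
    notch_max_mm: np.ndarray
    jsw_axis_xy_mm: np.ndarray | None = None


@dataclass
class ContactCurve:
    """Virtual-loading record: displacement and per-compartment contact area."""

    displacement_mm: np.ndarray
    contact_area_l_mm2: np.ndarray
    contact_area_m_mm2: np.ndarray
    spacing_mm: float = field(default=1.0)


# ---------------------------------------------------------------------------
# reference alignment
# ---------------------------------------------------------------------------

def _principal_basis(coords_mm: np.ndarray) -> np.ndarray:
    """Columns: medial-lateral, antero-posterior and long principal axes."""
    cov = np.cov(coords_mm.T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if (evals[2] - evals[1]) < 1e-6 * max(evals[2], 1e-300):
        raise ValueError("degenerate inertia tensor: no unique long axis")
    long_axis = evecs[:, 2]
    ml_axis = evecs[:, 1]     # second-largest spread -> medial-lateral (x)
    return np.column_stack([ml_axis, np.cross(long_axis, ml_axis), long_axis])


def align_to_reference(bone_mask: np.ndarray, spacing_mm: float,
                       which: str = "femur"):
    """Principal-axes pose of a bone relative to the canonical orientation.

    The canonical orientation has the bone's long axis on z and its
    medial-lateral axis on x.  Returns ``(pose, aligned_mask)`` where
    ``pose`` is the rigid transform mapping the canonical orientation to
    the observed one (yaw of the pose feeds the twist angle tau) and
    ``aligned_mask`` is the bone resampled into the canonical frame.
    Among the four sign choices of the principal axes the pose closest
    to the identity is selected, which resolves the ambiguity for
    near-upright scans.
    """
    if which not in ("femur", "tibia"):
        raise ValueError("which must be 'femur' or 'tibia'")
    bone_mask = np.asarray(bone_mask, dtype=bool)
    if not bone_mask.any():
        raise ValueError("align_to_reference: empty mask")
    coords = np.argwhere(bone_mask) * spacing_mm
    centroid = coords.mean(axis=0)
    B = _principal_basis(coords)

    best = None
    for sz in (1.0, -1.0):
        for sx in (1.0, -1.0):
            z = sz * B[:, 2]
            x = sx * B[:, 0]
            y = np.cross(z, x)
            pose = np.column_stack([x, y, z])  # canonical axes -> observed
            angle = np.arccos(np.clip((np.trace(pose) - 1.0) / 2.0, -1.0, 1.0))
            if best is None or angle < best[0]:
                best = (angle, pose)
    pose = best[1]
    transform = RigidTransform(pose, centroid - pose @ centroid)

    vol = LabelVolume(bone_mask.astype(np.int16), spacing_mm)
    aligned = resample_rigid(vol, transform.inverse(), "nearest").labels.astype(bool)
    log.info("align_to_reference[%s]: pose yaw/pitch/roll = %s deg", which,
             np.round(transform.euler_zyx_deg, 3))
    return transform, aligned


def twist_angle(transform_f: RigidTransform, transform_t: RigidTransform) -> float:
    """tau [deg] = yaw(femur pose) - yaw(tibia pose), wrapped to (-180, 180]."""
    tau = transform_f.yaw_deg - transform_t.yaw_deg
    tau = (tau + 180.0) % 360.0 - 180.0
    return float(tau if tau != -180.0 else 180.0)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def surface_height_map(mask: np.ndarray, spacing_mm: float,
                       direction: str = "distal") -> np.ndarray:
    """Extreme surface z (mm) per XY column; NaN for unoccupied columns.

    ``distal`` returns the lowest surface (femoral articular side),
    ``proximal`` the highest (tibial plateau side).
    """
    if direction not in ("distal", "proximal"):
        raise ValueError("direction must be 'distal' or 'proximal'")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("surface_height_map: empty mask")
    occ = mask.any(axis=2)
    nz = mask.shape[2]
    if direction == "distal":
        idx = np.argmax(mask, axis=2)               # first True from below
    else:
        idx = nz - 1 - np.argmax(mask[:, :, ::-1], axis=2)
    hm = np.where(occ, idx * spacing_mm, np.nan)
    return hm


def condyle_landmarks(height_map: np.ndarray, spacing_mm: float,
                      laterality: str = "right",
                      seed_x_mm: float | None = None) -> LandmarkSet:
    """Locate per-compartment surface minima and the interior maximum.

    The columns are split at ``seed_x_mm`` (default: occupancy-weighted
    centre of geometry); in each half the landmark is the centroid of
    all surface points within one voxel of that half's minimum z.  The
    notch (or tibial eminence) landmark is the centroid of the points
    within one voxel of the maximum z over the strip strictly between
    the two minima.  Raises if no interior maximum rises above the
    minima ("notch not found").
    """
    hm = np.asarray(height_map, dtype=float)
    occ = np.isfinite(hm)
    if not occ.any():
        raise ValueError("empty height map")
    xs = np.arange(hm.shape[0]) * spacing_mm
    ys = np.arange(hm.shape[1]) * spacing_mm
    if seed_x_mm is None:
        seed_x_mm = float((xs[:, None] * occ).sum() / occ.sum())

    tol = spacing_mm * (1.0 + 1e-9)

    def half_min(sel):
        vals = np.where(occ & sel, hm, np.nan)
        zmin = np.nanmin(vals)
        pts = np.argwhere(vals <= zmin + tol)
        centroid = np.array([xs[pts[:, 0]].mean(), ys[pts[:, 1]].mean(), zmin])
        return centroid

    low = xs[:, None] <= seed_x_mm
    lm_low = half_min(np.broadcast_to(low, hm.shape))
    lm_high = half_min(np.broadcast_to(~low, hm.shape))

    x0, x1 = sorted([lm_low[0], lm_high[0]])
    strip = (xs[:, None] > x0) & (xs[:, None] < x1)
    strip = np.broadcast_to(strip, hm.shape) & occ
    if not strip.any():
        raise ValueError("notch not found: no interior columns between minima")
    vals = np.where(strip, hm, np.nan)
    zmax = np.nanmax(vals)
    if zmax <= max(lm_low[2], lm_high[2]) + tol:
        raise ValueError("notch not found: no interior maximum between minima")
    pts = np.argwhere(vals >= zmax - tol)
    notch = np.array([xs[pts[:, 0]].mean(), ys[pts[:, 1]].mean(), zmax])

    # laterality: right knee -> lateral on the low-x side
    if laterality == "right":
        lat, med = lm_low, lm_high
    else:
        lat, med = lm_high, lm_low
    return LandmarkSet(lateral_min_mm=lat, medial_min_mm=med, notch_max_mm=notch)


def margin_angles(landmarks: LandmarkSet):
    """(sigma_L, sigma_M, rho) in degrees from a landmark set.

    sigma: coronal-projection angle between +z and the notch-to-minimum
    chord, in (0, 90].  rho: signed inclination of the lateral-to-medial
    minima line against the transverse plane, positive when the medial
    minimum is more proximal.
    """
    notch = landmarks.notch_max_mm
    sigmas = []
    for lm in (landmarks.lateral_min_mm, landmarks.medial_min_mm):
        dx = abs(lm[0] - notch[0])
        dz = notch[2] - lm[2]
        if dx < 1e-12 and abs(dz) < 1e-12:
            raise ValueError("coincident landmarks")
        sigmas.append(float(np.degrees(np.arctan2(dx, dz))))
    lat, med = landmarks.lateral_min_mm, landmarks.medial_min_mm
    dx = abs(med[0] - lat[0])
    if dx < 1e-12:
        raise ValueError("coincident condylar minima")
    rho = float(np.degrees(np.arctan2(med[2] - lat[2], dx)))
    return sigmas[0], sigmas[1], rho


def split_compartments(labels: LabelVolume, landmarks: LandmarkSet | None = None):
    """Lateral/medial partition of the grid at the notch sagittal plane.

    Returns ``(lateral_mask, medial_mask)``; their union is the full
    grid.  A voxel column lying exactly on the split plane (within half
    a voxel) is divided by its y-half as a tie-break, so a mirror-
    symmetric joint splits into equal compartments.  Without landmarks
    the split falls back to the centre-of-mass x with a warning.
    """
    nx, ny = labels.shape[0], labels.shape[1]
    s = labels.spacing_mm
    if landmarks is not None:
        x_split = landmarks.notch_max_mm[0]
    else:
        occ = labels.labels > 0
        if not occ.any():
            raise ValueError("empty label volume")
        warnings.warn("notch undefined; splitting at centre-of-mass x", stacklevel=2)
        x_split = float(np.argwhere(occ)[:, 0].mean() * s)
    xs = np.arange(nx) * s
    low = xs < x_split - s / 2.0
    on_plane = np.abs(xs - x_split) <= s / 2.0
    low_mask = np.zeros(labels.shape, dtype=bool)
    low_mask[low] = True
    if on_plane.any():
        half_y = np.arange(ny) < ny // 2
        low_mask[np.ix_(np.flatnonzero(on_plane), np.flatnonzero(half_y))] = True
    if labels.laterality == "right":
        return low_mask, ~low_mask
    return ~low_mask, low_mask


# ---------------------------------------------------------------------------
# joint space width and centre-of-mass vector
# ---------------------------------------------------------------------------

def jsw_axis(femur_mask: np.ndarray, spacing_mm: float, n_slices: int = 100):
    """Mean XY centre of geometry over the ``n_slices`` most distal femur slices."""
    femur_mask = np.asarray(femur_mask, dtype=bool)
    occupied_z = np.flatnonzero(femur_mask.any(axis=(0, 1)))
    if occupied_z.size == 0:
        raise ValueError("empty femur mask")
    if occupied_z.size < n_slices:
        warnings.warn(f"only {occupied_z.size} femur slices available "
                      f"(< {n_slices}); using all", stacklevel=2)
    use = occupied_z[:n_slices]
    cents = []
    for z in use:
        pts = np.argwhere(femur_mask[:, :, z])
        cents.append(pts.mean(axis=0))
    return np.mean(cents, axis=0) * spacing_mm


def joint_space_width(femur_mask: np.ndarray, tibia_mask: np.ndarray,
                      landmarks: LandmarkSet, spacing_mm: float):
    """(JSW_L, JSW_M) in mm: vertical landmark-to-tibia distances."""
    femur_mask = np.asarray(femur_mask, dtype=bool)
    tibia_mask = np.asarray(tibia_mask, dtype=bool)
    out = []
    for lm in (landmarks.lateral_min_mm, landmarks.medial_min_mm):
        i = int(round(lm[0] / spacing_mm))
        j = int(round(lm[1] / spacing_mm))
        zl = lm[2] / spacing_mm
        col = _tibia_top_below(tibia_mask, i, j, zl)
        if col is None:
            raise ValueError("no tibial voxel below the femoral landmark")
        out.append((zl - col) * spacing_mm)
    return float(out[0]), float(out[1])


def _tibia_top_below(tibia_mask, i, j, z_limit_vox):
    """Highest tibial z index below z_limit in column (i, j) or a 1-voxel neighbour."""
    nx, ny, _ = tibia_mask.shape
    for di, dj in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1),
                   (1, 1), (1, -1), (-1, 1), (-1, -1)):
        a, b = i + di, j + dj
        if not (0 <= a < nx and 0 <= b < ny):
            continue
        col = np.flatnonzero(tibia_mask[a, b, : int(np.floor(z_limit_vox)) + 1])
        if col.size:
            return int(col[-1])
    return None


def com_vector(femur_mask: np.ndarray, tibia_mask: np.ndarray, spacing_mm: float):
    """(lambda, alpha, beta, gamma, v): femur-minus-tibia COM vector.

    Uniform density voxel centroids; direction angles are the arccos of
    the direction cosines against +x, +y, +z, in [0, 180] degrees.
    """
    femur_mask = np.asarray(femur_mask, dtype=bool)
    tibia_mask = np.asarray(tibia_mask, dtype=bool)
    if not femur_mask.any() or not tibia_mask.any():
        raise ValueError("com_vector: empty mask")
    cf = np.argwhere(femur_mask).mean(axis=0) * spacing_mm
    ct = np.argwhere(tibia_mask).mean(axis=0) * spacing_mm
    v = cf - ct
    lam = float(np.linalg.norm(v))
    if lam == 0:
        raise ValueError("coincident centres of mass")
    ang = np.degrees(np.arccos(np.clip(v / lam, -1.0, 1.0)))
    return lam, float(ang[0]), float(ang[1]), float(ang[2]), v


def direction_cosine_residual(alpha_deg: float, beta_deg: float, gamma_deg: float) -> float:
    """|cos^2 a + cos^2 b + cos^2 g - 1| — the direction-angle identity check."""
    c = np.cos(np.radians([alpha_deg, beta_deg, gamma_deg]))
    return float(abs(np.sum(c ** 2) - 1.0))


# ---------------------------------------------------------------------------
# virtual loading
# ---------------------------------------------------------------------------

def virtual_loading(femur_union: np.ndarray, tibia_union: np.ndarray,
                    spacing_mm: float, split_x_mm: float,
                    laterality: str = "right", max_steps: int = 60) -> ContactCurve:
    """Stepwise virtual loading of the femur onto the tibia.

    The femur (bone + cartilage) is translated down one voxel per step;
    at each step the per-compartment contact area is the number of XY
    columns where the displaced femur overlaps the tibia, times
    spacing^2.  Compartment membership of a column follows the tibial
    side of the sagittal split plane.
    """
    femur_union = np.asarray(femur_union, dtype=bool)
    tibia_union = np.asarray(tibia_union, dtype=bool)
    if np.any(femur_union & tibia_union):
        raise ValueError("volumes initially intersecting")

    nz = femur_union.shape[2]
    f_occ = femur_union.any(axis=2)
    t_occ = tibia_union.any(axis=2)
    f_bot = np.where(f_occ, np.argmax(femur_union, axis=2), nz + 1).astype(float)
    f_top = np.where(f_occ, nz - 1 - np.argmax(femur_union[:, :, ::-1], axis=2), -1.0)
    t_bot = np.where(t_occ, np.argmax(tibia_union, axis=2), nz + 1).astype(float)
    t_top = np.where(t_occ, nz - 1 - np.argmax(tibia_union[:, :, ::-1], axis=2), -1.0)

    both = f_occ & t_occ
    xs = np.arange(femur_union.shape[0]) * spacing_mm
    low = np.broadcast_to((xs <= split_x_mm)[:, None], f_occ.shape)
    lat_cols = low if laterality == "right" else ~low

    area_l = np.zeros(max_steps + 1)
    area_m = np.zeros(max_steps + 1)
    for k in range(max_steps + 1):
        contact = both & (f_bot - k <= t_top) & (f_top - k >= t_bot)
        area_l[k] = np.sum(contact & lat_cols) * spacing_mm ** 2
        area_m[k] = np.sum(contact & ~lat_cols) * spacing_mm ** 2
    disp = np.arange(max_steps + 1) * spacing_mm
    log.info("virtual_loading: first contact L at %.3g mm, M at %.3g mm",
             disp[area_l > 0][0] if (area_l > 0).any() else np.nan,
             disp[area_m > 0][0] if (area_m > 0).any() else np.nan)
    return ContactCurve(disp, area_l, area_m, spacing_mm)


def contact_metrics(curve: ContactCurve, fit_window_steps: int = 10):
    """(chi_L, chi_M [mm], m_L, m_M [mm^2/mm]) from a contact curve.

    chi is the displacement at first non-zero contact area; m the
    least-squares slope of area against displacement over the window
    [chi, chi + fit_window_steps * spacing].  A compartment that never
    contacts is reported NaN.
    """
    out = []
    for area in (curve.contact_area_l_mm2, curve.contact_area_m_mm2):
        nz_idx = np.flatnonzero(np.asarray(area) > 0)
        if nz_idx.size == 0:
            out.extend([np.nan, np.nan])
            continue
        first = nz_idx[0]
        chi = float(curve.displacement_mm[first])
        stop = min(first + fit_window_steps + 1, len(area))
        d = np.asarray(curve.displacement_mm[first:stop], dtype=float)
        a = np.asarray(area[first:stop], dtype=float)
        if d.size < 2:
            out.extend([chi, np.nan])
            continue
        slope = float(np.polyfit(d, a, 1)[0])
        out.extend([chi, slope])
    return out[0], out[2], out[1], out[3]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def compute_joint_metrics(labels: LabelVolume, max_steps: int = 60,
                          fit_window_steps: int = 10,
                          include_cartilage_in_contact: bool = True,
                          align: bool = True) -> tuple:
    """All whole-joint metrics for a segmented joint.

    Returns ``(JointMetricsRecord, dict)`` where the dict carries the
    landmark sets, the contact curve and the alignment poses.
    """
    s = labels.spacing_mm
    femur = labels.mask(FEMUR)
    tibia = labels.mask(TIBIA)
    if not femur.any() or not tibia.any():
        raise ValueError("need both femur and tibia labels")

    rec = JointMetricsRecord()
    extras: dict = {}

    pose_f, _ = align_to_reference(femur, s, "femur")
    pose_t, _ = align_to_reference(tibia, s, "tibia")
    extras["pose_femur"] = pose_f
    extras["pose_tibia"] = pose_t
    rec.tau_deg = twist_angle(pose_f, pose_t)

    work = labels
    if align:
        ang = np.degrees(np.arccos(np.clip(
            (np.trace(pose_t.rotation) - 1.0) / 2.0, -1.0, 1.0)))
        if ang > 0.1:  # re-orient everything into the tibial reference frame
            work = resample_rigid(labels, pose_t.inverse(), "nearest")
            femur = work.mask(FEMUR)
            tibia = work.mask(TIBIA)

    axis = jsw_axis(femur, s)
    extras["jsw_axis_xy_mm"] = axis

    hm_f = surface_height_map(femur, s, "distal")
    lms_f = condyle_landmarks(hm_f, s, work.laterality, seed_x_mm=float(axis[0]))
    lms_f.jsw_axis_xy_mm = axis
    extras["landmarks_femur"] = lms_f
    rec.sigma_fl_deg, rec.sigma_fm_deg, rec.rho_deg = margin_angles(lms_f)

    hm_t = surface_height_map(tibia, s, "proximal")
    try:
        lms_t = condyle_landmarks(hm_t, s, work.laterality, seed_x_mm=float(axis[0]))
        extras["landmarks_tibia"] = lms_t
        rec.sigma_tl_deg, rec.sigma_tm_deg, _ = margin_angles(lms_t)
    except ValueError as exc:
        warnings.warn(f"tibial margin angles unavailable: {exc}", stacklevel=2)

    rec.jsw_l_mm, rec.jsw_m_mm = joint_space_width(femur, tibia, lms_f, s)

    (rec.lambda_mm, rec.alpha_deg, rec.beta_deg, rec.gamma_deg,
     extras["com_vector_mm"]) = com_vector(femur, tibia, s)

    if include_cartilage_in_contact:
        f_union = femur | work.mask(FEMORAL_CARTILAGE)
        t_union = tibia | work.mask(TIBIAL_CARTILAGE)
    else:
        f_union, t_union = femur, tibia
    curve = virtual_loading(f_union, t_union, s,
                            split_x_mm=float(lms_f.notch_max_mm[0]),
                            laterality=work.laterality, max_steps=max_steps)
    extras["contact_curve"] = curve
    (rec.chi_l_mm, rec.chi_m_mm,
     rec.m_l_mm2_per_mm, rec.m_m_mm2_per_mm) = contact_metrics(curve, fit_window_steps)
    return rec, extras
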