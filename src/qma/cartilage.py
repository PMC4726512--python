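"""Cartilage morphometry: 3D compartment metrics and 2D section metrics.

3D metrics per compartment (femoral/tibial x lateral/medial):

* ``Cg.Th`` [mm] — model-independent thickness (largest inscribed sphere),
  mean and SD over the cartilage voxels,
* ``Cg.V`` [mm^3] — voxel-count volume,
* ``Cg.S`` [mm^2] — triangulated iso-surface area of the closed boundary,
* ``Cg.S/Cg.V`` [mm^-1].

2D metrics on matched section images (the histology-comparison plane):
mean 2D thickness (largest inscribed disc, reported in um) and the mean
greyscale of the segmented region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._surface import mesh_surface_area
from ._thickness import local_thickness
from .volumes import LabelVolume, FEMORAL_CARTILAGE, TIBIAL_CARTILAGE

log = logging.getLogger("qma")

REGIONS = ("F.L", "F.M", "T.L", "T.M")


@dataclass
class CartilageMorphometry:
    """Per-compartment cartilage scalars (units in field names)."""

    region: str
    cg_th_mean_mm: float
    cg_th_sd_mm: float
    cg_v_mm3: float
    cg_s_mm2: float
    cg_s_over_v_per_mm: float

    def as_dict(self) -> dict:
        return {
            "region": self.region,
            "Cg.Th_mean [mm]": self.cg_th_mean_mm,
            "Cg.Th_SD [mm]": self.cg_th_sd_mm,
            "Cg.V [mm^3]": self.cg_v_mm3,
            "Cg.S [mm^2]": self.cg_s_mm2,
            "Cg.S/Cg.V [mm^-1]": self.cg_s_over_v_per_mm,
        }


@dataclass
class Section2DResult:
    """2D section outcomes: mean thickness in um and mean greyscale."""

    cg_th_2d_um: float
    mu_gr: float


def local_thickness_map(mask: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Local thickness map (mm) of a binary 3D region.

    Largest-inscribed-sphere definition; see :mod:`qma._thickness`.
    """
    return local_thickness(mask, spacing_mm)


def cartilage_metrics(labels: LabelVolume, region: str,
                      region_mask: np.ndarray | None = None) -> CartilageMorphometry:
    """Compute Cg.Th / Cg.V / Cg.S / Cg.S/Cg.V for one compartment.

    Parameters
    ----------
    labels : LabelVolume
    region : {"F.L", "F.M", "T.L", "T.M"}
    region_mask : ndarray of bool, optional
        Compartment membership mask (normally from
        :func:`qma.joint.split_compartments`).  When omitted, the
        laterality-resolved x-half of the volume is used.
    """
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    code = FEMORAL_CARTILAGE if region.startswith("F") else TIBIAL_CARTILAGE
    if region_mask is None:
        half = labels.lateral_half()
        region_mask = half if region.endswith("L") else ~half
    mask = labels.mask(code) & region_mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no cartilage voxels in region {region}")

    s = labels.spacing_mm
    cg_v = n * s ** 3  # integer count before scaling
    cg_s = mesh_surface_area(mask, s)
    th = local_thickness(mask, s)
    vals = th[mask]
    res = CartilageMorphometry(
        region=region,
        cg_th_mean_mm=float(vals.mean()),
        cg_th_sd_mm=float(vals.std(ddof=1)) if n > 1 else 0.0,
        cg_v_mm3=float(cg_v),
        cg_s_mm2=cg_s,
        cg_s_over_v_per_mm=float(cg_s / cg_v),
    )
    log.info("cartilage_metrics %s: n=%d Cg.Th=%.4f mm Cg.V=%.3f mm^3", region, n,
             res.cg_th_mean_mm, res.cg_v_mm3)
    return res


def thickness_2d(section_mask: np.ndarray, pixel_mm: float) -> float:
    """Mean 2D thickness (largest inscribed disc) of a section mask, in um."""
    section_mask = np.asarray(section_mask, dtype=bool)
    if section_mask.ndim != 2:
        raise ValueError("section_mask must be 2D")
    if not section_mask.any():
        raise ValueError("thickness_2d: empty mask")
    th = local_thickness(section_mask, pixel_mm)
    return float(th[section_mask].mean() * 1000.0)


def thickness_2d_map(section_mask: np.ndarray, pixel_mm: float) -> np.ndarray:
    """2D local thickness map in mm (un-averaged form of :func:`thickness_2d`)."""
    return local_thickness(np.asarray(section_mask, dtype=bool), pixel_mm)


def mean_grey(image: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of image values under a binary mask (muGr)."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("mean_grey: empty mask")
    return float(image[mask].mean())


def section_metrics(image: np.ndarray, mask: np.ndarray, pixel_mm: float) -> Section2DResult:
    """2D Cg.Th [um] and muGr for one section image + segmentation."""
    return Section2DResult(cg_th_2d_um=thickness_2d(mask, pixel_mm),
                           mu_gr=mean_grey(image, mask))
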