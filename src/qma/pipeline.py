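"""End-to-end orchestration with provenance logging.

``run_qma`` drives the whole chain on a segmented joint: filtering,
alignment, compartment split, cartilage + bone + whole-joint metrics,
and a deterministic JSON/CSV result bundle.  ``run_phantom_suite``
materialises the canonical validation phantoms with their ground-truth
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from . import __version__
from .bone import cortical_metrics, trabecular_metrics
from .cartilage import cartilage_metrics
from .joint import compute_joint_metrics, split_compartments
from .phantom import (OsteophyteBump, PhantomSpec, TrabecularSpec, make_joint_phantom,
                      make_plate, make_sphere, make_trabecular_block)
from .volumes import (FEMORAL_CARTILAGE, FEMUR, TIBIA, TIBIAL_CARTILAGE,
                      LabelVolume, gaussian_smooth, read_volume, write_volume)

log = logging.getLogger("qma")


@dataclass
class RunConfig:
    """Configuration of one QMA run (serialisable to/from YAML)."""

    labels_path: str | None = None
    scalar_path: str | None = None
    spacing_override_mm: float | None = None
    laterality: str = "right"
    filter_sigma: float = 1.2
    filter_support: int = 1
    contrast: str = "none"          # {none, sio, hexabrix}
    force_bone_morphometry: bool = False
    fit_window_steps: int = 10
    max_loading_steps: int = 60
    include_cartilage_in_contact: bool = True
    output_dir: str = "qma_out"
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)


def _bone_compartment_metrics(bone_mask, spacing_mm, region, seed):
    """Trabecular + cortical morphometry of one bone compartment.

    The total volume for normalisation is the hole-filled envelope of
    the compartment's bone mask (caller-defined masks can refine this).
    """
    tv = ndi.binary_fill_holes(bone_mask)
    res = trabecular_metrics(bone_mask, tv, spacing_mm, region=region, da_seed=seed)
    cort = cortical_metrics(bone_mask, tv, spacing_mm, region=region)
    res.ct_th_mm = cort.ct_th_mm
    res.ct_po_pct = cort.ct_po_pct
    return res


def run_qma(config: RunConfig, labels: LabelVolume | None = None):
    """Execute the full analysis; returns the result bundle as a dict.

    ``labels`` may be passed directly (e.g. a phantom); otherwise
    ``config.labels_path`` is read.  The bundle is written to
    ``config.output_dir`` as ``qma_results.json`` plus a flat CSV.
    """
    stage = "load"
    try:
        if labels is None:
            if config.labels_path is None:
                raise ValueError("no labels provided")
            labels = read_volume(config.labels_path, as_labels=True,
                                 spacing_override_mm=config.spacing_override_mm,
                                 laterality=config.laterality)
        scalar = None
        if config.scalar_path:
            scalar = read_volume(config.scalar_path,
                                 spacing_override_mm=config.spacing_override_mm)
            stage = "filter"
            scalar = gaussian_smooth(scalar, config.filter_sigma, config.filter_support)

        stage = "joint_metrics"
        rec, extras = compute_joint_metrics(
            labels, max_steps=config.max_loading_steps,
            fit_window_steps=config.fit_window_steps,
            include_cartilage_in_contact=config.include_cartilage_in_contact)

        stage = "compartments"
        lat, med = split_compartments(labels, extras.get("landmarks_femur"))

        stage = "cartilage"
        cart_rows = []
        for region, code, comp in (("F.L", FEMORAL_CARTILAGE, lat),
                                   ("F.M", FEMORAL_CARTILAGE, med),
                                   ("T.L", TIBIAL_CARTILAGE, lat),
                                   ("T.M", TIBIAL_CARTILAGE, med)):
            if not (labels.mask(code) & comp).any():
                warnings.warn(f"no cartilage in {region}; skipped", stacklevel=2)
                continue
            cart_rows.append(cartilage_metrics(labels, region, comp).as_dict())

        stage = "bone"
        bone_rows = []
        if config.contrast == "hexabrix" and not config.force_bone_morphometry:
            warnings.warn("bone morphometry skipped: contrast agent perfuses bone "
                          "tissue and corrupts Ct.Th/BS/BV/Tb.Th; use a "
                          "non-contrast scan or force_bone_morphometry",
                          stacklevel=2)
        else:
            for region, code, comp in (("F.L", FEMUR, lat), ("F.M", FEMUR, med),
                                       ("T.L", TIBIA, lat), ("T.M", TIBIA, med)):
                mask = labels.mask(code) & comp
                if not mask.any():
                    continue
                bone_rows.append(_bone_compartment_metrics(
                    mask, labels.spacing_mm, region, config.seed).as_dict())

        stage = "bundle"
        bundle = {
            "software": {"name": "qma", "version": __version__},
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "spacing_mm": labels.spacing_mm,
            "laterality": labels.laterality,
            "joint_metrics": {k: _jsonify(v) for k, v in rec.as_dict().items()},
            "cartilage": [{k: _jsonify(v) for k, v in row.items()} for row in cart_rows],
            "bone": [{k: _jsonify(v) for k, v in row.items()} for row in bone_rows],
            "contact_fit_window_steps": config.fit_window_steps,
            "tau_sign_convention": "femur yaw minus tibia yaw, ZYX Euler",
        }
    except Exception as exc:
        fp = "-"
        if labels is not None:
            fp = hashlib.sha256(np.ascontiguousarray(labels.labels)).hexdigest()[:12]
        raise RuntimeError(f"QMA stage '{stage}' failed (labels {fp}): {exc}") from exc

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "qma_results.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    _write_csv(bundle, out_dir / "qma_results.csv")
    curve = extras["contact_curve"]
    _write_curve_csv(curve, out_dir / "contact_curve.csv")
    log.info("run_qma complete -> %s", out_dir)
    bundle["_extras"] = extras
    return bundle


def _jsonify(v):
    if isinstance(v, (np.floating, float)):
        v = float(v)
        return None if np.isnan(v) else round(v, 9)
    if isinstance(v, (np.integer,)):
        return int(v)
    return v


def _write_csv(bundle, path: Path):
    rows = [("parameter", "unit", "region", "value", "config_hash")]
    for key, val in bundle["joint_metrics"].items():
        name, unit = key.rsplit(" [", 1)
        rows.append((name, unit.rstrip("]"), "joint", val, bundle["config_hash"]))
    for section in ("cartilage", "bone"):
        for row in bundle[section]:
            region = row["region"]
            for key, val in row.items():
                if key == "region":
                    continue
                name, unit = key.rsplit(" [", 1)
                rows.append((name, unit.rstrip("]"), region, val, bundle["config_hash"]))
    path.write_text("\n".join(",".join(str(c) for c in r) for r in rows) + "\n")


def _write_curve_csv(curve, path: Path):
    rows = ["displacement_mm,contact_area_L_mm2,contact_area_M_mm2"]
    for d, al, am in zip(curve.displacement_mm, curve.contact_area_l_mm2,
                         curve.contact_area_m_mm2):
        rows.append(f"{d:.6f},{al:.9f},{am:.9f}")
    path.write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# phantom suite
# ---------------------------------------------------------------------------

def run_phantom_suite(out_dir, seed: int = 0, spacing_mm: float = 0.05,
                      write_volumes: bool = True) -> dict:
    """Generate the canonical validation phantoms + truth manifests.

    Contents: plate, sphere, isotropic and anisotropic trabecular
    blocks, the symmetric joint, and a three-size osteophyte sweep.
    Returns ``{name: (LabelVolume, PhantomTruth)}`` and, when
    ``write_volumes`` is set, writes NIfTI volumes and JSON manifests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suite = {}
    # plate/sphere/trabecular primitives keep their canonical spacings so
    # the printed truth values stay comparable across suites
    suite["plate"] = make_plate(10, 60, 0.05)
    suite["sphere"] = make_sphere(0.5, 0.02)
    suite["trabecular_iso"] = make_trabecular_block(
        TrabecularSpec(seed=seed), 0.05)
    suite["trabecular_aniso"] = make_trabecular_block(
        TrabecularSpec(correlation_length_mm=(0.15, 0.15, 0.3), seed=seed + 1),
        0.05)
    _, lab, truth = make_joint_phantom(PhantomSpec(spacing_mm=spacing_mm, seed=seed))
    suite["joint"] = (lab, truth)
    for i, r in enumerate((0.45, 0.65, 0.85)):
        _, lab, truth = make_joint_phantom(PhantomSpec(
            spacing_mm=spacing_mm, seed=seed,
            osteophyte_bump=OsteophyteBump(radius_mm=r)))
        suite[f"joint_osteophyte_r{int(r * 100):03d}"] = (lab, truth)

    if write_volumes:
        for name, (lab, truth) in suite.items():
            write_volume(lab, out_dir / f"{name}.nii.gz")
            (out_dir / f"{name}_truth.json").write_text(
                json.dumps(truth.manifest(), indent=2, sort_keys=True) + "\n")
    log.info("phantom suite: %d phantoms -> %s", len(suite), out_dir)
    return suite
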