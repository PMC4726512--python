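"""Shared phantom fixtures (session-scoped: phantoms are reused widely)."""

import numpy as np
import pytest

from qma.joint import compute_joint_metrics
from qma.phantom import (OsteophyteBump, PhantomSpec, make_joint_phantom,
                         make_sphere)


@pytest.fixture(scope="session")
def joint_phantom():
    """Symmetric two-condyle joint phantom at 0.05 mm with ground truth."""
    vol, lab, truth = make_joint_phantom(PhantomSpec())
    return vol, lab, truth


@pytest.fixture(scope="session")
def joint_record(joint_phantom):
    """Whole-joint metrics computed once on the symmetric phantom."""
    _, lab, _ = joint_phantom
    rec, extras = compute_joint_metrics(lab)
    return rec, extras


@pytest.fixture(scope="session")
def yawed_phantom():
    """Joint phantom with a +5 degree yaw applied to the femur only."""
    _, lab, truth = make_joint_phantom(PhantomSpec(femur_yaw_deg=5.0))
    return lab, truth


@pytest.fixture(scope="session")
def osteophyte_sweep():
    """Phantoms with growing medial osteophyte bumps (4 protruding radii)."""
    out = []
    for r in (0.35, 0.5, 0.65, 0.8):
        _, lab, truth = make_joint_phantom(
            PhantomSpec(osteophyte_bump=OsteophyteBump(radius_mm=r)))
        out.append((r, lab, truth))
    return out


@pytest.fixture(scope="session")
def sphere_r25():
    """Digitised ball of radius 0.5 mm at 0.02 mm spacing (r = 25 voxels)."""
    return make_sphere(0.5, 0.02)


@pytest.fixture(scope="session")
def coarse_joint():
    """Joint phantom at 0.1 mm spacing (fast end-to-end pipeline runs)."""
    _, lab, truth = make_joint_phantom(PhantomSpec(spacing_mm=0.1))
    return lab, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
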