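"""Triangulated iso-surface area of binary masks (shared helper)."""

from __future__ import annotations

import numpy as np

__all__ = ["mesh_surface_area"]


def mesh_surface_area(mask: np.ndarray, spacing_mm: float) -> float:
    """Area (mm^2) of the 0.5-level triangulated iso-surface of a binary mask.

    The mask is padded so surfaces lying on the array boundary are closed.
    The binary mask is lightly smoothed (Gaussian, 0.5 voxel) before
    meshing: marching cubes on a raw binary field overestimates curved
    surfaces by ~9% (staircase facets), while the smoothed field meshes
    a sphere to within ~4% and an axis-aligned box to within ~3%.  When
    the object is too small to survive smoothing the raw binary mesh is
    used; such sub-resolution objects carry a documented low bias (a
    one-voxel cube meshes to an octahedron, ~29% of its voxel-face
    area).
    """
    import scipy.ndimage as ndi
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mesh_surface_area: empty mask")
    padded = np.pad(mask, 2).astype(np.float32)
    field = ndi.gaussian_filter(padded, 0.5)
    if field.max() <= 0.5:
        field = padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5,
                                                spacing=(float(spacing_mm),) * 3)
    return float(measure.mesh_surface_area(verts, faces))
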