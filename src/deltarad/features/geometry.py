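"""Size and global shape descriptors computed from the mask alone."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from ..errors import DegenerateLesionError
from ..io import LesionMask

_FACE_STRUCT = np.array(
    [
        [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
        [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
    ],
    dtype=bool,
)


def surface_voxels(mask: LesionMask) -> np.ndarray:
    """Indices (n, 3) of foreground voxels with >= 1 of 6 face-neighbours outside.

    Out-of-grid counts as outside, so voxels on the array border are surface.
    """
    fg = mask.data > 0
    interior = binary_erosion(fg, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(fg & ~interior)


def _world(coords: np.ndarray, mask: LesionMask) -> np.ndarray:
    return coords * np.asarray(mask.spacing) + np.asarray(mask.origin)


def tumor_volume(mask: LesionMask) -> float:
    """Foreground voxel count times the voxel volume, mm^3."""
    if mask.n_foreground == 0:
        raise DegenerateLesionError("empty mask")
    return float(mask.n_foreground * np.prod(mask.spacing))


def max_diameter(mask: LesionMask) -> float:
    """Largest 3D Euclidean distance (mm) between two surface-voxel centers."""
    if mask.n_foreground == 0:
        raise DegenerateLesionError("empty mask")
    pts = _world(surface_voxels(mask), mask)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 400:
        # the diameter is attained on the convex hull
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets: brute force below
    return float(pdist(pts).max())


def boundary_radius_std(mask: LesionMask) -> float:
    """Population std (mm) of centroid-to-surface-voxel distances.

    Zero for a perfect sphere; grows with surface irregularity/elongation.
    """
    if mask.n_foreground == 0:
        raise DegenerateLesionError("empty mask")
    centroid = _world(np.argwhere(mask.data > 0), mask).mean(axis=0)
    surf = _world(surface_voxels(mask), mask)
    d = np.linalg.norm(surf - centroid, axis=1)
    return float(d.std())
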