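"""Shape-index surface histogram (Shape_SI1..SI9).

The binary mask is Gaussian-smoothed into an implicit function F; at each
surface voxel the principal curvatures (kappa1 >= kappa2, outward-positive,
so a sphere has kappa1 = kappa2 = 1/r > 0) are computed from the gradient
and Hessian of F via the level-set shape operator. The local shape index

    s = 1/2 - (1/pi) * atan2(kappa1 + kappa2, kappa1 - kappa2)   in [0, 1]

classifies the surface patch; under this mapping a spherical cap (dome)
lands near s = 0 (bin SI1), a cup near s = 1 (SI9), and a flat/degenerate
patch at s = 1/2 (the SI5 fallback bin). SIk is the fraction of surface
voxels whose s falls in the k-th of 9 equal-width bins; the fractions
partition the surface and sum to 1.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy.ndimage import gaussian_filter

from ..errors import DegenerateLesionError
from ..io import LesionMask
from .geometry import surface_voxels

_N_BINS = 9
_EPS_GRAD = 1e-8


def shape_index_values(mask: LesionMask, smoothing_sigma: float = 1.5) -> np.ndarray:
    """Shape index s in [0, 1] at each surface voxel."""
    if mask.n_foreground == 0:
        raise DegenerateLesionError("empty mask")
    spacing = np.asarray(mask.spacing)
    sigma_vox = smoothing_sigma / spacing
    F = gaussian_filter(mask.data.astype(np.float64), sigma=sigma_vox)

    grads = np.gradient(F, *spacing)  # dF/dz, dF/dy, dF/dx in world units
    hess = [[None] * 3 for _ in range(3)]
    for a in range(3):
        second = np.gradient(grads[a], *spacing)
        for b in range(3):
            hess[a][b] = second[b]

    surf = surface_voxels(mask)
    zi, yi, xi = surf[:, 0], surf[:, 1], surf[:, 2]
    g = np.stack([grads[a][zi, yi, xi] for a in range(3)], axis=1)  # (n, 3)
    H = np.empty((len(surf), 3, 3))
    for a in range(3):
        for b in range(3):
            H[:, a, b] = hess[a][b][zi, yi, xi]

    gnorm = np.linalg.norm(g, axis=1)
    s = np.full(len(surf), 0.5)  # flat-surface fallback
    ok = gnorm > _EPS_GRAD
    if ok.any():
        n_in = g[ok] / gnorm[ok, None]  # unit gradient (points inward: F high inside)
        # orthonormal tangent basis via Gram-Schmidt against n_in
        ref = np.zeros_like(n_in)
        ref[np.abs(n_in[:, 0]) < 0.9, 0] = 1.0
        ref[np.abs(n_in[:, 0]) >= 0.9, 1] = 1.0
        t1 = ref - (np.sum(ref * n_in, axis=1)[:, None]) * n_in
        t1 /= np.linalg.norm(t1, axis=1)[:, None]
        t2 = np.cross(n_in, t1)
        # level-set shape operator with outward-positive sign convention
        M = -H[ok] / gnorm[ok, None, None]
        a11 = np.einsum("ni,nij,nj->n", t1, M, t1)
        a12 = np.einsum("ni,nij,nj->n", t1, M, t2)
        a22 = np.einsum("ni,nij,nj->n", t2, M, t2)
        mean = 0.5 * (a11 + a22)
        half = np.sqrt(np.clip((0.5 * (a11 - a22)) ** 2 + a12**2, 0.0, None))
        k1, k2 = mean + half, mean - half
        s[ok] = 0.5 - np.arctan2(k1 + k2, k1 - k2) / np.pi
    return np.clip(s, 0.0, 1.0)


def shape_index_features(mask: LesionMask, smoothing_sigma: float = 1.5) -> Dict[str, float]:
    """Fractions of surface voxels per shape-index bin; sums to 1."""
    s = shape_index_values(mask, smoothing_sigma)
    bins = np.minimum((s * _N_BINS).astype(int), _N_BINS - 1)
    counts = np.bincount(bins, minlength=_N_BINS).astype(float)
    fracs = counts / counts.sum()
    return {f"Shape_SI{k + 1}": float(fracs[k]) for k in range(_N_BINS)}
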