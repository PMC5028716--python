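"""Masked per-slice 2D filtering helpers shared by Laws and Gabor energies.

Filtering is applied to each axial (z) slice with half-sample-symmetric
("reflect") boundary handling. For efficiency the computation is restricted
to the mask's bounding box expanded by the kernel half-width; every mask
voxel is far enough from the crop edges (or sits at a true image edge) that
the result is identical to filtering the full slice.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve


def masked_slice_energy(data: np.ndarray, mask: np.ndarray, kernel: np.ndarray) -> float:
    """Sum of squared 2D cross-correlation responses over mask voxels."""
    hy, hx = kernel.shape[0] // 2, kernel.shape[1] // 2
    zs, ys, xs = np.nonzero(mask)
    z0, z1 = int(zs.min()), int(zs.max())
    ny, nx = data.shape[1], data.shape[2]
    y0, y1 = max(int(ys.min()) - hy, 0), min(int(ys.max()) + hy, ny - 1)
    x0, x1 = max(int(xs.min()) - hx, 0), min(int(xs.max()) + hx, nx - 1)

    flipped = kernel[::-1, ::-1]  # correlation via convolution
    total = 0.0
    for z in range(z0, z1 + 1):
        m = mask[z, y0 : y1 + 1, x0 : x1 + 1]
        if not m.any():
            continue
        sl = data[z, y0 : y1 + 1, x0 : x1 + 1]
        padded = np.pad(sl, ((hy, hy), (hx, hx)), mode="symmetric")
        resp = fftconvolve(padded, flipped, mode="valid")
        total += float(np.sum(resp[m > 0] ** 2))
    return total
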