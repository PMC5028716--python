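"""Gray-level co-occurrence matrix (GLCM) texture features in 3D.

Lesion intensities are quantized into equal-width bins over the masked
[min, max] range; co-occurrences are counted for voxel pairs separated by
``distance * direction`` along the 13 unique (pairwise non-antiparallel) 3D
offset directions, symmetrized, and normalized to sum 1. Per-direction
statistics are aggregated (mean / std / range) across the 13 directions,
mirroring the usual rotation-invariant Haralick protocol.

Entropies use the natural logarithm; gray levels enter the statistics as
0-based bin indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from ..errors import DegenerateLesionError, ParameterError
from ..io import ImageVolume, LesionMask, validate_pair

#: The 13 unique 3D neighbour directions (z, y, x); no two are antiparallel.
DIRECTIONS_13: Tuple[Tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

#: Supported co-occurrence statistics (15).
GLCM_STATISTICS: Tuple[str, ...] = (
    "Contrast",
    "Dissimilarity",
    "Homogeneity",
    "ASM",
    "MaxProb",
    "Entropy",
    "Correlation",
    "ClusterShade",
    "ClusterProminence",
    "SumAverage",
    "SumEntropy",
    "DiffEntropy",
    "Autocorrelation",
    "IMC1",
    "MCC",
)

_AGGREGATIONS = ("mean", "std", "range")


@dataclass(frozen=True)
class GLCMConfig:
    n_levels: int = 32
    distances: Tuple[int, ...] = (1, 2, 4)
    symmetric: bool = True

    def __post_init__(self):
        if self.n_levels < 2:
            raise ParameterError("n_levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ParameterError("distances must be >= 1")


def quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width quantization of `values` into 0..n_levels-1 over [min, max]."""
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        return np.zeros(values.shape, dtype=np.intp)
    q = np.floor((values - vmin) / (vmax - vmin) * n_levels).astype(np.intp)
    return np.clip(q, 0, n_levels - 1)


def _pair_counts(q: np.ndarray, mask: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Count co-occurring quantized pairs (x, x + offset) with both ends masked."""
    src, dst = [], []
    for axis, d in enumerate(offset):
        size = q.shape[axis]
        if abs(d) >= size:
            return np.zeros((n_levels, n_levels), dtype=np.int64)
        src.append(slice(max(0, -d), size - max(0, d)))
        dst.append(slice(max(0, d), size + min(0, d)))
    src, dst = tuple(src), tuple(dst)
    valid = (mask[src] > 0) & (mask[dst] > 0)
    a = q[src][valid]
    b = q[dst][valid]
    counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
    return counts.reshape(n_levels, n_levels)


def compute_glcm(
    volume: ImageVolume,
    mask: LesionMask,
    distance: int,
    direction: Tuple[int, int, int],
    config: GLCMConfig = GLCMConfig(),
) -> np.ndarray:
    """Normalized (symmetrized) co-occurrence matrix for one offset."""
    validate_pair(volume, mask)
    if tuple(direction) not in DIRECTIONS_13:
        raise ParameterError(f"direction {direction} is not one of the 13 directions")
    q = quantize(volume.data[mask.data > 0], config.n_levels)
    qgrid = np.zeros(volume.shape, dtype=np.intp)
    qgrid[mask.data > 0] = q
    return _glcm_from_quantized(qgrid, mask.data, distance, direction, config)


def _glcm_from_quantized(qgrid, maskdata, distance, direction, config) -> np.ndarray:
    offset = tuple(int(distance) * d for d in direction)
    counts = _pair_counts(qgrid, maskdata, offset, config.n_levels).astype(np.float64)
    if config.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DegenerateLesionError(
            f"no valid voxel pairs for offset {offset} (degenerate co-occurrence matrix)"
        )
    return counts / total


def glcm_statistics(P: np.ndarray) -> Dict[str, float]:
    """All supported statistics of one normalized co-occurrence matrix.

    Degenerate fallbacks (single occupied gray level): IMC1 -> 0, MCC -> 1,
    Correlation -> 0.
    """
    n = P.shape[0]
    idx = np.arange(n, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(idx * px))
    mu_y = float(np.sum(idx * py))
    var_x = float(np.sum((idx - mu_x) ** 2 * px))
    var_y = float(np.sum((idx - mu_y) ** 2 * py))
    nz = P > 0

    out: Dict[str, float] = {}
    out["Contrast"] = float(np.sum((i - j) ** 2 * P))
    out["Dissimilarity"] = float(np.sum(np.abs(i - j) * P))
    out["Homogeneity"] = float(np.sum(P / (1.0 + (i - j) ** 2)))
    out["ASM"] = float(np.sum(P**2))
    out["MaxProb"] = float(P.max())
    hxy = float(-np.sum(P[nz] * np.log(P[nz])))
    out["Entropy"] = hxy
    if var_x > 0 and var_y > 0:
        out["Correlation"] = float(
            np.sum((i - mu_x) * (j - mu_y) * P) / np.sqrt(var_x * var_y)
        )
    else:
        out["Correlation"] = 0.0
    out["ClusterShade"] = float(np.sum((i + j - mu_x - mu_y) ** 3 * P))
    out["ClusterProminence"] = float(np.sum((i + j - mu_x - mu_y) ** 4 * P))

    # diagonal-band marginals
    ksum = np.arange(2 * n - 1, dtype=np.float64)
    p_sum = np.zeros(2 * n - 1)
    p_diff = np.zeros(n)
    ij_sum = (np.arange(n)[:, None] + np.arange(n)[None, :]).ravel()
    ij_diff = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).ravel()
    np.add.at(p_sum, ij_sum, P.ravel())
    np.add.at(p_diff, ij_diff, P.ravel())
    out["SumAverage"] = float(np.sum(ksum * p_sum))
    out["SumEntropy"] = float(-np.sum(p_sum[p_sum > 0] * np.log(p_sum[p_sum > 0])))
    out["DiffEntropy"] = float(-np.sum(p_diff[p_diff > 0] * np.log(p_diff[p_diff > 0])))
    out["Autocorrelation"] = float(np.sum(i * j * P))

    # Informational measure of correlation 1
    hx = float(-np.sum(px[px > 0] * np.log(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log(py[py > 0])))
    outer = px[:, None] * py[None, :]
    valid = nz & (outer > 0)
    hxy1 = float(-np.sum(P[valid] * np.log(outer[valid])))
    denom = max(hx, hy)
    out["IMC1"] = (hxy - hxy1) / denom if denom > 0 else 0.0

    # Maximum correlation coefficient
    active = px > 0
    if active.sum() < 2:
        out["MCC"] = 1.0
    else:
        Psub = P[np.ix_(active, active)]
        pxs = px[active]
        pys = py[active]
        Q = (Psub / pxs[:, None]) @ (Psub / pys[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        second = eig[1] if len(eig) > 1 else 0.0
        out["MCC"] = float(np.sqrt(np.clip(second, 0.0, 1.0)))
    return out


def glcm_direction_table(
    volume: ImageVolume,
    mask: LesionMask,
    config: GLCMConfig = GLCMConfig(),
    statistics: Sequence[str] = GLCM_STATISTICS,
) -> Dict[int, Dict[str, np.ndarray]]:
    """Per-direction statistic values for every configured distance.

    Returns {distance: {statistic: array of per-direction values}}; directions
    with no valid voxel pair (tiny masks) are dropped from the array. Shared
    by :func:`glcm_feature` and the batch extractor so the 13 matrices per
    distance are built once.
    """
    validate_pair(volume, mask)
    for s in statistics:
        if s not in GLCM_STATISTICS:
            raise ParameterError(f"unsupported GLCM statistic '{s}'")
    qgrid = np.zeros(volume.shape, dtype=np.intp)
    inside = mask.data > 0
    qgrid[inside] = quantize(volume.data[inside], config.n_levels)

    # restrict to the mask bounding box for speed
    zs, ys, xs = np.nonzero(inside)
    box = tuple(
        slice(int(c.min()), int(c.max()) + 1) for c in (zs, ys, xs)
    )
    qbox, mbox = qgrid[box], mask.data[box]

    table: Dict[int, Dict[str, np.ndarray]] = {}
    for dist in config.distances:
        per_stat: Dict[str, list] = {s: [] for s in statistics}
        for direction in DIRECTIONS_13:
            try:
                P = _glcm_from_quantized(qbox, mbox, dist, direction, config)
            except DegenerateLesionError:
                continue
            stats = glcm_statistics(P)
            for s in statistics:
                per_stat[s].append(stats[s])
        table[dist] = {s: np.asarray(v) for s, v in per_stat.items()}
    return table


def _aggregate(values: np.ndarray, aggregation: str) -> float:
    if aggregation not in _AGGREGATIONS:
        raise ParameterError(f"aggregation must be one of {_AGGREGATIONS}")
    if values.size == 0:
        return 0.0  # no direction had a valid pair; documented fallback
    if aggregation == "mean":
        return float(values.mean())
    if aggregation == "std":
        return float(values.std())
    return float(values.max() - values.min())


def glcm_feature(
    volume: ImageVolume,
    mask: LesionMask,
    statistic: str,
    distance: int,
    aggregation: str = "mean",
    config: GLCMConfig = GLCMConfig(),
) -> float:
    """One aggregated co-occurrence feature, e.g. GLCM_IMC1-mean-d1."""
    cfg = GLCMConfig(
        n_levels=config.n_levels, distances=(int(distance),), symmetric=config.symmetric
    )
    table = glcm_direction_table(volume, mask, cfg, statistics=(statistic,))
    return _aggregate(table[int(distance)][statistic], aggregation)
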