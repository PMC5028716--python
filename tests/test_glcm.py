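"""Co-occurrence features against an independent brute-force oracle."""

import numpy as np
import pytest

from deltarad import GLCMConfig
from deltarad.features import (
    DIRECTIONS_13,
    GLCM_STATISTICS,
    compute_glcm,
    glcm_feature,
    glcm_statistics,
)
from deltarad.errors import DegenerateLesionError
from conftest import make_pair


# ---------------------------------------------------------------------------
# brute-force oracle: explicit pair enumeration + plain-loop statistics


def brute_quantize(image, mask, n_levels):
    vals = image[mask > 0]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(image.shape, dtype=int)
    for idx in np.ndindex(image.shape):
        if mask[idx]:
            if hi == lo:
                q[idx] = 0
            else:
                q[idx] = min(int((image[idx] - lo) / (hi - lo) * n_levels), n_levels - 1)
    return q


def brute_glcm(image, mask, n_levels, distance, direction, symmetric=True):
    q = brute_quantize(image, mask, n_levels)
    off = tuple(distance * d for d in direction)
    counts = np.zeros((n_levels, n_levels))
    for idx in np.ndindex(image.shape):
        if not mask[idx]:
            continue
        nb = tuple(i + o for i, o in zip(idx, off))
        if all(0 <= n < s for n, s in zip(nb, image.shape)) and mask[nb]:
            counts[q[idx], q[nb]] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total if total > 0 else None


def brute_statistics(P):
    n = len(P)
    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    py = [sum(P[i][j] for i in range(n)) for j in range(n)]
    mx = sum(i * px[i] for i in range(n))
    my = sum(j * py[j] for j in range(n))
    vx = sum((i - mx) ** 2 * px[i] for i in range(n))
    vy = sum((j - my) ** 2 * py[j] for j in range(n))
    log = np.log
    out = {
        "Contrast": sum((i - j) ** 2 * P[i][j] for i in range(n) for j in range(n)),
        "Dissimilarity": sum(abs(i - j) * P[i][j] for i in range(n) for j in range(n)),
        "Homogeneity": sum(P[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)),
        "ASM": sum(P[i][j] ** 2 for i in range(n) for j in range(n)),
        "MaxProb": max(P[i][j] for i in range(n) for j in range(n)),
        "Entropy": -sum(
            P[i][j] * log(P[i][j]) for i in range(n) for j in range(n) if P[i][j] > 0
        ),
        "ClusterShade": sum(
            (i + j - mx - my) ** 3 * P[i][j] for i in range(n) for j in range(n)
        ),
        "ClusterProminence": sum(
            (i + j - mx - my) ** 4 * P[i][j] for i in range(n) for j in range(n)
        ),
        "Autocorrelation": sum(i * j * P[i][j] for i in range(n) for j in range(n)),
    }
    out["Correlation"] = (
        sum((i - mx) * (j - my) * P[i][j] for i in range(n) for j in range(n))
        / np.sqrt(vx * vy)
        if vx > 0 and vy > 0
        else 0.0
    )
    psum = [sum(P[i][k - i] for i in range(n) if 0 <= k - i < n) for k in range(2 * n - 1)]
    pdiff = [
        sum(P[i][j] for i in range(n) for j in range(n) if abs(i - j) == k) for k in range(n)
    ]
    out["SumAverage"] = sum(k * psum[k] for k in range(2 * n - 1))
    out["SumEntropy"] = -sum(p * log(p) for p in psum if p > 0)
    out["DiffEntropy"] = -sum(p * log(p) for p in pdiff if p > 0)
    hx = -sum(p * log(p) for p in px if p > 0)
    hy = -sum(p * log(p) for p in py if p > 0)
    hxy = out["Entropy"]
    hxy1 = -sum(
        P[i][j] * log(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if P[i][j] > 0 and px[i] * py[j] > 0
    )
    out["IMC1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    active = [i for i in range(n) if px[i] > 0]
    if len(active) < 2:
        out["MCC"] = 1.0
    else:
        m = len(active)
        Q = np.zeros((m, m))
        for a, i in enumerate(active):
            for b, j in enumerate(active):
                Q[a, b] = sum(
                    P[i][k] * P[j][k] / (px[i] * py[k]) for k in active if py[k] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        out["MCC"] = float(np.sqrt(min(max(eig[1], 0.0), 1.0)))
    return out


# ---------------------------------------------------------------------------


def test_printed_1d_toy_example():
    # row [1, 1, 2, 3] at 3 levels, d=1 along x, symmetric:
    # pairs {(1,1),(1,2),(2,3)} + transpose -> P(1,1)=2/6, off-diagonals 1/6
    data = np.array([[[1.0, 1.0, 2.0, 3.0]]])
    vol, mask = make_pair(data, np.ones_like(data))
    P = compute_glcm(vol, mask, 1, (0, 0, 1), GLCMConfig(n_levels=3, distances=(1,)))
    expected = np.array([[2, 1, 0], [1, 0, 1], [0, 1, 0]]) / 6.0
    np.testing.assert_allclose(P, expected)


def test_matrix_is_normalized_and_symmetric(rng):
    data = rng.normal(size=(5, 5, 5))
    mask = np.ones_like(data)
    P = compute_glcm(*make_pair(data, mask), 1, (1, 1, -1), GLCMConfig(n_levels=8))
    assert P.min() >= 0
    assert P.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(P, P.T)


def test_imc1_zero_for_independent_marginals():
    px = np.array([0.2, 0.5, 0.3])
    P = np.outer(px, px)
    assert glcm_statistics(P)["IMC1"] == pytest.approx(0.0, abs=1e-12)


def test_mcc_one_for_diagonal_2x2():
    # Q eigenvalues {1, 1} -> MCC = 1
    P = np.array([[0.5, 0.0], [0.0, 0.5]])
    assert glcm_statistics(P)["MCC"] == pytest.approx(1.0)


def test_mcc_bounded_in_unit_interval(rng):
    for _ in range(20):
        M = rng.random((6, 6))
        P = M / M.sum()
        assert 0.0 <= glcm_statistics(P)["MCC"] <= 1.0


def test_single_gray_level_fallbacks():
    vol, mask = make_pair(np.full((3, 4, 4), 5.0), np.ones((3, 4, 4)))
    P = compute_glcm(vol, mask, 1, (0, 0, 1), GLCMConfig(n_levels=4))
    stats = glcm_statistics(P)
    assert stats["IMC1"] == 0.0
    assert stats["MCC"] == 1.0
    assert stats["Contrast"] == 0.0
    assert stats["Correlation"] == 0.0


@pytest.mark.parametrize("distance", [1, 4])
@pytest.mark.parametrize("statistic", GLCM_STATISTICS)
def test_statistics_match_brute_force_oracle(rng, statistic, distance):
    data = np.round(rng.normal(size=(6, 6, 6)) * 10)
    mask = (rng.random((6, 6, 6)) > 0.2).astype(np.uint8)
    vol, m = make_pair(data, mask)
    cfg = GLCMConfig(n_levels=5, distances=(distance,))
    per_dir = []
    for direction in DIRECTIONS_13:
        Pb = brute_glcm(data, mask, 5, distance, direction)
        if Pb is None:
            continue
        Pi = compute_glcm(vol, m, distance, direction, cfg)
        np.testing.assert_allclose(Pi, Pb, atol=1e-12)
        per_dir.append(brute_statistics(Pb)[statistic])
    per_dir = np.asarray(per_dir)
    for agg, expected in (
        ("mean", per_dir.mean()),
        ("std", per_dir.std()),
        ("range", per_dir.max() - per_dir.min()),
    ):
        got = glcm_feature(vol, m, statistic, distance, agg, cfg)
        assert got == pytest.approx(expected, abs=1e-9)


def test_range_zero_for_isotropic_toy():
    vol, mask = make_pair(np.full((4, 4, 4), 1.0), np.ones((4, 4, 4)))
    assert glcm_feature(vol, mask, "Contrast", 1, "range") == 0.0


def test_no_valid_pairs_is_degenerate():
    data = np.zeros((3, 3, 3))
    mask = np.zeros((3, 3, 3))
    mask[1, 1, 1] = 1  # single voxel: no pair in any direction
    vol, m = make_pair(data, mask)
    with pytest.raises(DegenerateLesionError):
        compute_glcm(vol, m, 1, (0, 0, 1))
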