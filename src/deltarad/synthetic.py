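"""Synthetic CT lesion phantoms with a mutation-dependent response model.

The study's clinical cohort (paired pre/post-therapy chest CTs with EGFR
mutation labels) is emulated by rendering soft-tissue lesions embedded in
lung parenchyma:

* a perturbed-ellipsoid lesion with a sigmoid radial margin of controllable
  width,
* an intralesional stationary Gaussian random field (white noise convolved
  with a Gaussian kernel) giving texture with a controllable correlation
  length,
* i.i.d. additive scan noise,
* a treatment-response model in which sensitizing-mutant lesions shrink more
  (log-normal post/pre volume ratio with lower mean), their margins blur and
  their texture smooths, while wild-type lesions stay roughly constant,
* same-day test-retest pairs sharing geometry and plateaus, differing only
  in the noise realization and a sub-voxel translation of the continuous
  model.

All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.polynomial import legendre
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import GeometryError, ParameterError
from .io import ImageVolume, LesionMask, SubjectStudy

_N_BUMP_LOBES = 4  # band-limited surface perturbation, Legendre degrees 1..4


@dataclass(frozen=True)
class LesionParams:
    """Parameters of one rendered lesion.

    radii : ellipsoid semi-axes (z, y, x), mm
    bumpiness : amplitude of the low-order angular surface perturbation,
        as a fraction of the local radius
    lesion_hu / parenchyma_hu : plateau intensities, HU
    margin_width : sigmoid transition width w, mm; the radial profile is
        ``parenchyma + (lesion - parenchyma) / (1 + exp(4 t / w))`` with t the
        signed radial distance to the surface, so the maximum density slope
        is (lesion - parenchyma) / w  [HU/mm]
    texture_sigma : std of the intralesional random field, HU
    texture_corr_len : Gaussian correlation length of the field, mm
    noise_sigma : std of the i.i.d. scan noise, HU
    """

    radii: Tuple[float, float, float] = (8.0, 8.0, 8.0)
    bumpiness: float = 0.15
    lesion_hu: float = 30.0
    parenchyma_hu: float = -780.0
    margin_width: float = 1.0
    texture_sigma: float = 25.0
    texture_corr_len: float = 2.0
    noise_sigma: float = 20.0

    def __post_init__(self):
        if any(r <= 0 for r in self.radii):
            raise ParameterError(f"radii must be positive, got {self.radii}")
        if self.margin_width <= 0:
            raise ParameterError("margin_width must be > 0")
        if self.texture_corr_len <= 0:
            raise ParameterError("texture_corr_len must be > 0")
        if self.noise_sigma < 0 or self.texture_sigma < 0:
            raise ParameterError("noise/texture sigmas must be >= 0")


@dataclass(frozen=True)
class ResponseModel:
    """Label-conditional treatment-response law.

    Post/pre volume ratios are log-normal; defaults give mutants a mean
    ratio well below wild-type (E[mutant] < E[wt]). Mutant lesions also get
    blurrier margins (margin_width multiplied) and smoother texture
    (texture_corr_len multiplied) after treatment.
    """

    mutant_volume_ratio: Tuple[float, float] = (float(np.log(0.55)), 0.25)
    wt_volume_ratio: Tuple[float, float] = (float(np.log(0.98)), 0.08)
    mutant_margin_widening: float = 1.8
    mutant_texture_smoothing: float = 1.5

    def __post_init__(self):
        for meanlog, sdlog in (self.mutant_volume_ratio, self.wt_volume_ratio):
            if sdlog < 0:
                raise ParameterError("sdlog must be >= 0")
        if self.mutant_margin_widening <= 0 or self.mutant_texture_smoothing <= 0:
            raise ParameterError("response multipliers must be > 0")


def _bump_field(dirs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Band-limited angular perturbation: sum of Legendre P_l(d . u_l), l=1..4.

    Normalized so the field stays within [-1, 1]; `dirs` is (..., 3) unit
    vectors. The lobe axes and weights are drawn from `rng` (consumed even
    when bumpiness is zero, to keep the stream layout stable).
    """
    axes = rng.standard_normal((_N_BUMP_LOBES, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    coeffs = rng.standard_normal(_N_BUMP_LOBES)
    total = np.abs(coeffs).sum()
    if total == 0:
        return np.zeros(dirs.shape[:-1])
    out = np.zeros(dirs.shape[:-1])
    for l in range(_N_BUMP_LOBES):
        c = np.zeros(l + 2)
        c[l + 1] = 1.0
        out += coeffs[l] * legendre.legval(dirs @ axes[l], c)
    return out / total


def render_lesion(
    params: LesionParams,
    grid_spacing: float = 1.0,
    seed: int = 0,
    grid_shape: Tuple[int, int, int] = (64, 64, 64),
    shift_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_seed: Optional[int] = None,
) -> Tuple[ImageVolume, LesionMask]:
    """Render one lesion phantom on an isotropic grid.

    The continuous model (surface, margin, texture) is a function of `seed`;
    `shift_mm` translates it by a world offset before voxelization, and
    `noise_seed` (default: derived from `seed`) controls only the additive
    scan noise — together these produce test-retest pairs.
    """
    rng = np.random.default_rng(seed)
    spacing = (float(grid_spacing),) * 3
    shape = tuple(int(n) for n in grid_shape)

    # Containment: lesion + margin transition + 5 mm context must fit.
    half_extent = min(n * grid_spacing / 2.0 for n in shape)
    reach = max(params.radii) * (1 + abs(params.bumpiness)) + 2 * params.margin_width + 5.0
    if reach + max(abs(s) for s in shift_mm) > half_extent:
        raise GeometryError(
            f"lesion reach {reach:.1f} mm exceeds grid half-extent {half_extent:.1f} mm"
        )

    center = np.array([(n - 1) / 2.0 * grid_spacing for n in shape]) + np.asarray(shift_mm)
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * grid_spacing for n in shape], indexing="ij"),
        axis=-1,
    )
    rel = coords - center
    r = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.where(r[..., None] > 0, rel / np.maximum(r, 1e-12)[..., None], 0.0)

    # Directional surface radius: ellipsoid radius modulated by bump field.
    radii = np.asarray(params.radii, dtype=float)
    inv = np.sqrt(np.sum((dirs / radii) ** 2, axis=-1))
    r_ell = np.where(inv > 0, 1.0 / np.maximum(inv, 1e-12), radii.min())
    bump = _bump_field(dirs, rng)
    surface_r = r_ell * (1.0 + params.bumpiness * bump)

    t = r - surface_r  # signed radial distance, positive outside
    w = params.margin_width
    membership = np.empty_like(t)
    inner, outer = t <= -2 * w, t >= 2 * w
    mid = ~(inner | outer)
    membership[inner] = 1.0
    membership[outer] = 0.0
    membership[mid] = 1.0 / (1.0 + np.exp(4.0 * t[mid] / w))

    image = params.parenchyma_hu + (params.lesion_hu - params.parenchyma_hu) * membership

    # Intralesional texture: white noise smoothed to the correlation length,
    # sampled at the (possibly shifted) model coordinates so it moves with
    # the lesion.
    white = rng.standard_normal(shape)
    if params.texture_sigma > 0:
        field = gaussian_filter(white, sigma=params.texture_corr_len / grid_spacing)
        std = field.std()
        if std > 0:
            field = field * (params.texture_sigma / std)
        if any(s != 0 for s in shift_mm):
            idx = np.indices(shape, dtype=float)
            sample_at = [idx[a] - shift_mm[a] / grid_spacing for a in range(3)]
            field = map_coordinates(field, sample_at, order=1, mode="nearest")
        image = image + field * membership

    noise_rng = np.random.default_rng(seed + 1 if noise_seed is None else noise_seed)
    if params.noise_sigma > 0:
        image = image + noise_rng.standard_normal(shape) * params.noise_sigma

    mask = (t <= 0).astype(np.uint8)
    return (
        ImageVolume(data=image, spacing=spacing),
        LesionMask(data=mask, spacing=spacing),
    )


def _sample_params(
    rng: np.random.Generator,
    base: LesionParams,
    radius_range: Tuple[float, float],
) -> LesionParams:
    radii = tuple(rng.uniform(*radius_range, size=3))
    return dataclasses.replace(base, radii=radii)


def generate_cohort(
    n_mutant: int,
    n_wt: int,
    base_params: Optional[LesionParams] = None,
    response: Optional[ResponseModel] = None,
    seed: int = 0,
    grid_spacing: float = 1.0,
    grid_shape: Tuple[int, int, int] = (64, 64, 64),
    radius_range: Tuple[float, float] = (5.0, 15.0),
) -> List[SubjectStudy]:
    """Generate a labelled cohort of baseline/follow-up lesion pairs.

    Each subject's baseline radii are uniform over `radius_range` per axis;
    the follow-up lesion is the same continuous lesion re-rendered with radii
    scaled by ratio**(1/3), the ratio drawn from the label's volume-ratio
    law, and (for mutants) widened margins and smoothed texture.
    """
    if n_mutant + n_wt < 2:
        raise ParameterError("cohort needs at least 2 subjects")
    base = base_params or LesionParams()
    resp = response or ResponseModel()
    rng = np.random.default_rng(seed)

    studies: List[SubjectStudy] = []
    labels = [1] * n_mutant + [0] * n_wt
    for i, label in enumerate(labels):
        pre_params = _sample_params(rng, base, radius_range)
        geom_seed = int(rng.integers(0, 2**31 - 1))
        noise_pre = int(rng.integers(0, 2**31 - 1))
        noise_post = int(rng.integers(0, 2**31 - 1))
        meanlog, sdlog = resp.mutant_volume_ratio if label else resp.wt_volume_ratio
        ratio = float(np.exp(rng.normal(meanlog, sdlog)))

        post_params = dataclasses.replace(
            pre_params,
            radii=tuple(r * ratio ** (1.0 / 3.0) for r in pre_params.radii),
            margin_width=pre_params.margin_width
            * (resp.mutant_margin_widening if label else 1.0),
            texture_corr_len=pre_params.texture_corr_len
            * (resp.mutant_texture_smoothing if label else 1.0),
        )
        pre = render_lesion(pre_params, grid_spacing, geom_seed, grid_shape, noise_seed=noise_pre)
        post = render_lesion(post_params, grid_spacing, geom_seed, grid_shape, noise_seed=noise_post)
        studies.append(
            SubjectStudy(subject_id=f"sub{i:03d}", label=label, pre=pre, post=post)
        )
    return studies


def generate_test_retest(
    n: int,
    base_params: Optional[LesionParams] = None,
    seed: int = 0,
    grid_spacing: float = 1.0,
    grid_shape: Tuple[int, int, int] = (64, 64, 64),
    radius_range: Tuple[float, float] = (5.0, 15.0),
    max_shift_voxels: float = 0.5,
) -> List[Tuple[Tuple[ImageVolume, LesionMask], Tuple[ImageVolume, LesionMask]]]:
    """Generate same-day repeat-scan pairs.

    Both scans of a pair share lesion geometry, texture and plateaus; the
    second differs by an independent noise realization and a sub-voxel
    translation uniform in (-max_shift_voxels, +max_shift_voxels) per axis
    applied to the continuous model before voxelization.
    """
    if n < 2:
        raise ParameterError("need at least 2 test-retest pairs")
    base = base_params or LesionParams()
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        params = _sample_params(rng, base, radius_range)
        geom_seed = int(rng.integers(0, 2**31 - 1))
        noise_a = int(rng.integers(0, 2**31 - 1))
        noise_b = int(rng.integers(0, 2**31 - 1))
        shift = rng.uniform(-max_shift_voxels, max_shift_voxels, size=3) * grid_spacing
        scan1 = render_lesion(params, grid_spacing, geom_seed, grid_shape, noise_seed=noise_a)
        scan2 = render_lesion(
            params, grid_spacing, geom_seed, grid_shape,
            shift_mm=tuple(shift), noise_seed=noise_b,
        )
        pairs.append((scan1, scan2))
    return pairs
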