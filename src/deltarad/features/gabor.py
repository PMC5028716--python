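"""Gabor texture-energy features.

A Gabor filter is an oriented Gaussian envelope modulated by a sinusoidal
carrier; the real part is applied per axial slice and the energy is the sum
of squared responses over lesion voxels. Orientation is measured in-plane
from the +x (column) axis toward +y (row), in degrees; the wavelength is the
carrier period in pixels; the envelope width follows from the half-response
spatial-frequency bandwidth in octaves (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import gabor_kernel

from ..errors import DegenerateLesionError, ParameterError
from ..io import ImageVolume, LesionMask, validate_pair
from ._conv import masked_slice_energy


@dataclass(frozen=True)
class GaborParams:
    orientation_deg: float
    wavelength_px: float
    bandwidth: float = 1.0

    def __post_init__(self):
        if self.wavelength_px < 2:
            raise ParameterError("wavelength_px must be >= 2 (Nyquist)")
        if not 0 <= self.orientation_deg < 180:
            raise ParameterError("orientation_deg must lie in [0, 180)")


def gabor_kernel_2d(params: GaborParams) -> np.ndarray:
    """Real part of the complex Gabor kernel for the given parameters."""
    k = gabor_kernel(
        frequency=1.0 / params.wavelength_px,
        theta=np.deg2rad(params.orientation_deg),
        bandwidth=params.bandwidth,
    )
    return np.real(k)


def gabor_energy(volume: ImageVolume, mask: LesionMask, params: GaborParams) -> float:
    """Sum over lesion voxels of the squared per-slice Gabor response."""
    validate_pair(volume, mask)
    if mask.n_foreground == 0:
        raise DegenerateLesionError("empty mask")
    return masked_slice_energy(volume.data, mask.data, gabor_kernel_2d(params))
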