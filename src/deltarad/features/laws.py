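"""Laws texture-energy features.

The five classic 1D basis vectors — Level L5, Edge E5, Spot S5, Ripple R5,
Wave W5 — generate 5x5 kernels by outer products. The bank holds the 14
zero-sum kernels: the 10 symmetrized cross-products (u'v + v'u)/2 over
unordered pairs u != v, ordered lexicographically with L < E < S < R < W
(ids 1-10), followed by the four zero-mean self-products E5'E5, S5'S5,
R5'R5, W5'W5 (ids 11-14). L5'L5 is excluded as non-zero-mean. A named-alias
map allows remapping external filter numberings onto these ids.

Filtering is 2D per axial slice (CT is axially acquired); the energy is the
sum of squared responses over all lesion voxels across slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from ..errors import DegenerateLesionError, ParameterError
from ..io import ImageVolume, LesionMask, validate_pair
from ._conv import masked_slice_energy

LAWS_VECTORS: Dict[str, np.ndarray] = {
    "L": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
    "W": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}

_ORDER = "LESRW"


@dataclass(frozen=True)
class LawsFilterBank:
    """The 14 zero-sum Laws kernels, keyed by stable integer ids 1-14."""

    kernels: Tuple[np.ndarray, ...]
    names: Tuple[str, ...]

    def __len__(self) -> int:
        return len(self.kernels)

    def kernel(self, filter_id: int) -> np.ndarray:
        if not 1 <= filter_id <= len(self.kernels):
            raise ParameterError(f"Laws filter id must be 1..{len(self.kernels)}")
        return self.kernels[filter_id - 1]


def build_laws_filters() -> LawsFilterBank:
    kernels, names = [], []
    # ids 1-10: symmetrized cross-products, lexicographic over unordered pairs
    for i, a in enumerate(_ORDER):
        for b in _ORDER[i + 1 :]:
            u, v = LAWS_VECTORS[a], LAWS_VECTORS[b]
            kernels.append((np.outer(u, v) + np.outer(v, u)) / 2.0)
            names.append(f"{a}5{b}5")
    # ids 11-14: zero-mean self-products
    for a in "ESRW":
        u = LAWS_VECTORS[a]
        kernels.append(np.outer(u, u))
        names.append(f"{a}5{a}5")
    return LawsFilterBank(kernels=tuple(kernels), names=tuple(names))


_BANK = build_laws_filters()


def laws_energy(volume: ImageVolume, mask: LesionMask, filter_id: int) -> float:
    """Sum over lesion voxels of the squared per-slice Laws filter response."""
    validate_pair(volume, mask)
    if mask.n_foreground == 0:
        raise DegenerateLesionError("empty mask")
    return masked_slice_energy(volume.data, mask.data, _BANK.kernel(filter_id))
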