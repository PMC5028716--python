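"""Declarative feature manifest and the batch extractor.

A :class:`FeatureManifest` is an ordered list of (feature class, parameter
grid) entries that expands to a duplicate-free list of feature names; the
default manifest totals 183 features:

    12 size/shape   Volume, Max_Diameter, Boundary_Radius_Std, Shape_SI1-9
     6 sigmoid      Offset/Slope/Amplitude means at d = 3 and 5 mm
    14 Laws         Laws_Energy-1 .. -14
    16 Gabor        orientations {0, 45, 90, 135} deg x wavelengths {3, 5, 7, 9} px
   135 GLCM         15 statistics x distances {1, 2, 4} x {mean, std, range}

Manifests round-trip through YAML; only the default total is contractual,
the composition is data-driven configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import yaml

from ..errors import DeltaRadError, ParameterError
from ..io import ImageVolume, LesionMask, validate_pair
from .gabor import GaborParams, gabor_energy
from .geometry import boundary_radius_std, max_diameter, tumor_volume
from .glcm import GLCM_STATISTICS, GLCMConfig, _aggregate, glcm_direction_table
from .laws import laws_energy
from .margin import SigmoidConfig, sigmoid_margin_features
from .shape import shape_index_features

_SIGMOID_STAT_KEYS = {"Offset": "offset_mean", "Slope": "slope_mean", "Amplitude": "amplitude_mean"}


def _default_entries() -> List[dict]:
    return [
        {"class": "volume"},
        {"class": "max_diameter"},
        {"class": "boundary_radius_std"},
        {"class": "shape_index", "smoothing_sigma": 1.5},
        {
            "class": "sigmoid",
            "half_lengths": [3.0, 5.0],
            "stats": ["Offset", "Slope", "Amplitude"],
            "step_mm": 0.5,
        },
        {"class": "laws", "ids": list(range(1, 15))},
        {
            "class": "gabor",
            "orientations": [0.0, 45.0, 90.0, 135.0],
            "wavelengths": [3.0, 5.0, 7.0, 9.0],
            "bandwidth": 1.0,
        },
        {
            "class": "glcm",
            "statistics": list(GLCM_STATISTICS),
            "distances": [1, 2, 4],
            "aggregations": ["mean", "std", "range"],
            "n_levels": 32,
        },
    ]


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered catalogue of feature-class entries with parameter grids."""

    entries: List[dict] = field(default_factory=_default_entries)

    def __post_init__(self):
        names = self.names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ParameterError(f"manifest expands to duplicate names: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.names())

    def names(self) -> List[str]:
        out: List[str] = []
        for entry in self.entries:
            cls = entry["class"]
            if cls == "volume":
                out.append("Volume")
            elif cls == "max_diameter":
                out.append("Max_Diameter")
            elif cls == "boundary_radius_std":
                out.append("Boundary_Radius_Std")
            elif cls == "shape_index":
                out.extend(f"Shape_SI{k}" for k in range(1, 10))
            elif cls == "sigmoid":
                for L in entry.get("half_lengths", [5.0]):
                    for stat in entry.get("stats", ["Offset", "Slope"]):
                        out.append(f"Sigmoid-{stat}-Mean-d{_fmt(L)}")
            elif cls == "laws":
                aliases = entry.get("aliases") or {}
                for fid in entry.get("ids", list(range(1, 15))):
                    shown = aliases.get(fid, fid)
                    out.append(f"Laws_Energy-{shown}")
            elif cls == "gabor":
                for o in entry.get("orientations", [135.0]):
                    for w in entry.get("wavelengths", [3.0]):
                        out.append(f"Gabor_Energy-dir{_fmt(o)}-w{_fmt(w)}")
            elif cls == "glcm":
                for stat in entry.get("statistics", list(GLCM_STATISTICS)):
                    for agg in entry.get("aggregations", ["mean"]):
                        for d in entry.get("distances", [1, 4]):
                            out.append(f"GLCM_{stat}-{agg}-d{d}")
            else:
                raise ParameterError(f"unknown feature class '{cls}'")
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"features": self.entries}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(entries=doc["features"])


def _fmt(x: float) -> str:
    """Compact numeric tag: 3.0 -> '3', 2.5 -> '2.5'."""
    xf = float(x)
    return str(int(xf)) if xf == int(xf) else str(xf)


def default_manifest() -> FeatureManifest:
    return FeatureManifest()


def extract_features(
    volume: ImageVolume, mask: LesionMask, manifest: FeatureManifest = None
) -> Dict[str, float]:
    """Evaluate every manifest entry; ordered name -> finite value map.

    Any sub-extractor failure is re-raised naming the offending feature
    class so a cohort run points at the culprit.
    """
    manifest = manifest or default_manifest()
    validate_pair(volume, mask)
    values: Dict[str, float] = {}
    for entry in manifest.entries:
        cls = entry["class"]
        try:
            _eval_entry(volume, mask, entry, values)
        except DeltaRadError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise DeltaRadError(f"feature class '{cls}' failed: {exc}") from exc
    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise DeltaRadError(f"non-finite feature values: {bad[:5]}")
    expected = manifest.names()
    assert list(values) == expected, "extractor/name expansion out of sync"
    return values


def _eval_entry(volume, mask, entry, out: Dict[str, float]) -> None:
    cls = entry["class"]
    if cls == "volume":
        out["Volume"] = tumor_volume(mask)
    elif cls == "max_diameter":
        out["Max_Diameter"] = max_diameter(mask)
    elif cls == "boundary_radius_std":
        out["Boundary_Radius_Std"] = boundary_radius_std(mask)
    elif cls == "shape_index":
        out.update(shape_index_features(mask, entry.get("smoothing_sigma", 1.5)))
    elif cls == "sigmoid":
        for L in entry.get("half_lengths", [5.0]):
            cfg = SigmoidConfig(
                half_length_mm=float(L),
                step_mm=float(entry.get("step_mm", 0.5)),
                smoothing_sigma_mm=float(entry.get("smoothing_sigma", 1.5)),
                max_lines=entry.get("max_lines", 200),
            )
            res = sigmoid_margin_features(volume, mask, cfg)
            for stat in entry.get("stats", ["Offset", "Slope"]):
                out[f"Sigmoid-{stat}-Mean-d{_fmt(L)}"] = res[_SIGMOID_STAT_KEYS[stat]]
    elif cls == "laws":
        aliases = entry.get("aliases") or {}
        for fid in entry.get("ids", list(range(1, 15))):
            shown = aliases.get(fid, fid)
            out[f"Laws_Energy-{shown}"] = laws_energy(volume, mask, int(fid))
    elif cls == "gabor":
        for o in entry.get("orientations", [135.0]):
            for w in entry.get("wavelengths", [3.0]):
                params = GaborParams(
                    orientation_deg=float(o),
                    wavelength_px=float(w),
                    bandwidth=float(entry.get("bandwidth", 1.0)),
                )
                out[f"Gabor_Energy-dir{_fmt(o)}-w{_fmt(w)}"] = gabor_energy(volume, mask, params)
    elif cls == "glcm":
        stats = entry.get("statistics", list(GLCM_STATISTICS))
        cfg = GLCMConfig(
            n_levels=int(entry.get("n_levels", 32)),
            distances=tuple(int(d) for d in entry.get("distances", [1, 4])),
            symmetric=bool(entry.get("symmetric", True)),
        )
        table = glcm_direction_table(volume, mask, cfg, statistics=stats)
        for stat in stats:
            for agg in entry.get("aggregations", ["mean"]):
                for d in cfg.distances:
                    out[f"GLCM_{stat}-{agg}-d{d}"] = _aggregate(table[d][stat], agg)
    else:
        raise ParameterError(f"unknown feature class '{cls}'")
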