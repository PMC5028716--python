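"""End-to-end study orchestration.

``run_study`` mirrors the clinical workflow: obtain a cohort of paired
baseline/follow-up lesion scans (from a manifest CSV or the synthetic
generator), resample to isotropic spacing, extract the radiomic feature
catalogue at both time points, form the delta table, select features by
CV ranking + correlation pruning, and screen every selected feature for
association with the mutation label (ROC AUC + Mann-Whitney p) at all
three time points. ``run_stability`` evaluates per-feature test-retest ICC
on same-day repeat-scan pairs.

All outputs are deterministic functions of (config, seed); reports carry
the generator seed, a config hash and the package version so every number
is traceable to its run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import DeltaFeatureSelector, delta_table, feature_columns, make_feature_table
from .errors import ParameterError, StageError
from .features import FeatureManifest, default_manifest, extract_features
from .io import read_cohort_manifest, resample_isotropic
from .stats import bh_adjust, correlation_matrix, icc, roc_auc
from .synthetic import LesionParams, ResponseModel, generate_cohort, generate_test_retest

_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one study run (exactly one cohort source).

    Synthetic source: ``n_mutant``/``n_wt`` subjects on a
    ``grid_spacing``-mm grid with ``seed``. File source: ``cohort_manifest``
    CSV (columns subject_id, label, pre_image, pre_mask, post_image,
    post_mask). ``target_spacing`` triggers isotropic resampling before
    extraction; None keeps the native grid.
    """

    n_mutant: int = 20
    n_wt: int = 20
    seed: int = 7
    grid_spacing: float = 1.0
    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    radius_range: Tuple[float, float] = (5.0, 15.0)
    lesion: Dict = field(default_factory=dict)
    response: Dict = field(default_factory=dict)
    cohort_manifest: Optional[str] = None
    target_spacing: Optional[float] = None
    feature_manifest: Optional[str] = None
    k: int = 15
    corr_threshold: float = 0.95
    corr_method: str = "spearman"
    icc_model: str = "icc1"
    n_retest: int = 20
    retest_seed: int = 11
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "radius_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def load_feature_manifest(self) -> FeatureManifest:
        if self.feature_manifest is None:
            return default_manifest()
        return FeatureManifest.from_yaml(self.feature_manifest)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


@_stage("cohort")
def _load_cohort(config: StudyConfig):
    if config.cohort_manifest is not None:
        return read_cohort_manifest(config.cohort_manifest)
    return generate_cohort(
        n_mutant=config.n_mutant,
        n_wt=config.n_wt,
        base_params=LesionParams(**config.lesion),
        response=ResponseModel(**config.response),
        seed=config.seed,
        grid_spacing=config.grid_spacing,
        grid_shape=config.grid_shape,
        radius_range=config.radius_range,
    )


@_stage("extract")
def extract_cohort_tables(studies, manifest: FeatureManifest, target_spacing=None):
    """Feature tables at both time points for a list of SubjectStudy."""
    tables = {}
    for tp in ("pre", "post"):
        rows = []
        for study in studies:
            vol, msk = getattr(study, tp)
            if target_spacing is not None:
                vol, msk = resample_isotropic(vol, msk, target_spacing)
            rows.append(extract_features(vol, msk, manifest))
        tables[tp] = make_feature_table(
            rows, [s.subject_id for s in studies], [s.label for s in studies], tp
        )
    return tables["pre"], tables["post"]


@_stage("auc")
def _auc_report(tables: Dict[str, pd.DataFrame], panel: List[str]) -> pd.DataFrame:
    rows = []
    for tp, table in tables.items():
        results = [roc_auc(table[f], table["label"], feature=f) for f in panel]
        q = bh_adjust([r.p_two_sided for r in results])
        for r, qv in zip(results, q):
            rows.append(
                {
                    "feature": r.feature,
                    "timepoint": tp,
                    "auc": r.auc,
                    "p": r.p_two_sided,
                    "q_bh_supplementary": qv,
                    "direction": r.direction,
                    "n_pos": r.n_pos,
                    "n_neg": r.n_neg,
                    "method": r.method,
                }
            )
    return pd.DataFrame(rows)


def run_study(config: StudyConfig, out_dir=None) -> Dict:
    """Run the full delta-radiomics study; returns the report bundle.

    When an output directory is configured the bundle is also written as
    CSVs plus ``run_manifest.json``; files appear only after every stage
    succeeded, so a failed run leaves no partial reports.
    """
    studies = _load_cohort(config)
    manifest = _load_manifest(config)
    pre, post = extract_cohort_tables(studies, manifest, config.target_spacing)
    delta = _delta(pre, post)
    selector = _select(config, delta)
    panel = selector.selected_features_
    tables = {"pre": pre, "post": post, "delta": delta}
    auc_report = _auc_report(tables, panel)
    corr = _corr(config, delta, panel)

    bundle = {
        "features_pre": pre,
        "features_post": post,
        "features_delta": delta,
        "selection_report": selector.report_,
        "selected_features": panel,
        "auc_report": auc_report,
        "correlation_matrix": corr,
        "run_manifest": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
            "n_subjects": len(studies),
            "n_features": len(manifest),
            "selected_features": panel,
        },
    }
    out = out_dir or config.out_dir
    if out is not None:
        _write_bundle(bundle, Path(out))
    return bundle


@_stage("manifest")
def _load_manifest(config):
    return config.load_feature_manifest()


@_stage("delta")
def _delta(pre, post):
    return delta_table(pre, post)


@_stage("select")
def _select(config, delta):
    return DeltaFeatureSelector(
        k=config.k, corr_threshold=config.corr_threshold, method=config.corr_method
    ).fit(delta)


@_stage("correlation")
def _corr(config, delta, panel):
    return correlation_matrix(delta[panel], method=config.corr_method)


def _write_bundle(bundle: Dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for key in ("features_pre", "features_post", "features_delta"):
        bundle[key].to_csv(out / f"{key}.csv", float_format=_FLOAT_FMT)
    bundle["selection_report"].to_csv(
        out / "selection_report.csv", index=False, float_format=_FLOAT_FMT
    )
    bundle["auc_report"].to_csv(out / "auc_report.csv", index=False, float_format=_FLOAT_FMT)
    bundle["correlation_matrix"].to_csv(
        out / "correlation_matrix.csv", float_format=_FLOAT_FMT
    )
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(bundle["run_manifest"], fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Test-retest stability


def run_stability(config: StudyConfig, pairs=None, out_dir=None) -> Dict:
    """Per-feature test-retest ICC over same-day repeat-scan pairs.

    ``pairs`` is a list of ((vol, mask), (vol, mask)); by default synthetic
    pairs are generated from the config. The report covers every feature in
    the active manifest, sorted by decreasing ICC, with a mean +/- std
    summary across features.
    """
    manifest = _load_manifest(config)
    if pairs is None:
        pairs = _make_retest_pairs(config)
    if len(pairs) < 2:
        raise StageError("stability", ParameterError("need >= 2 test-retest pairs"))
    try:
        rows_1, rows_2 = [], []
        for (v1, m1), (v2, m2) in pairs:
            if config.target_spacing is not None:
                v1, m1 = resample_isotropic(v1, m1, config.target_spacing)
                v2, m2 = resample_isotropic(v2, m2, config.target_spacing)
            rows_1.append(extract_features(v1, m1, manifest))
            rows_2.append(extract_features(v2, m2, manifest))
        t1 = pd.DataFrame(rows_1)
        t2 = pd.DataFrame(rows_2)
        results = [
            icc(t1[f], t2[f], model=config.icc_model, feature=f) for f in t1.columns
        ]
    except StageError:
        raise
    except Exception as exc:
        raise StageError("stability", exc) from exc
    report = pd.DataFrame(
        [
            {"feature": r.feature, "icc": r.icc, "n_pairs": r.n_pairs, "model": r.model}
            for r in results
        ]
    ).sort_values(["icc", "feature"], ascending=[False, True], ignore_index=True)
    finite = report["icc"].to_numpy()
    finite = finite[np.isfinite(finite)]
    bundle = {
        "icc_report": report,
        "summary": {
            "icc_mean": float(finite.mean()),
            "icc_std": float(finite.std()),
            "n_features": int(len(report)),
            "n_pairs": int(len(pairs)),
            "model": report["model"].iloc[0],
            "seed": config.retest_seed,
            "config_hash": config.config_hash(),
            "version": __version__,
        },
    }
    out = out_dir or config.out_dir
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "icc_report.csv", index=False, float_format=_FLOAT_FMT)
        with open(out / "stability_summary.json", "w") as fh:
            json.dump(bundle["summary"], fh, indent=2, sort_keys=True)
    return bundle


@_stage("retest-cohort")
def _make_retest_pairs(config: StudyConfig):
    return generate_test_retest(
        n=config.n_retest,
        base_params=LesionParams(**config.lesion),
        seed=config.retest_seed,
        grid_spacing=config.grid_spacing,
        grid_shape=config.grid_shape,
        radius_range=config.radius_range,
    )
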