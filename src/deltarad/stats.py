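"""Biomarker screening statistics: ROC AUC, correlation matrices, ICC.

AUC is computed through the Mann-Whitney U identity AUC = U / (n_pos *
n_neg) with ties counted 1/2, the positive class being label 1
(sensitizing-mutant); the two-sided p-value uses exact enumeration for
small tie-free problems and the tie-corrected normal approximation
otherwise. Test-retest stability uses the single-measurement intraclass
correlation (default the one-way random-effects form ICC(1,1), the standard
choice when the same protocol produces both scans); the estimator label is
recorded in every result.

No multiple-testing correction is applied in the headline screening; a
Benjamini-Hochberg column is available as clearly supplementary output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ClassError, PairingError, ParameterError

_EXACT_LIMIT = 400


@dataclass(frozen=True)
class AUCResult:
    feature: str
    auc: float
    p_two_sided: float
    direction: int  # +1: higher values in mutants, -1: lower
    n_pos: int
    n_neg: int
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class ICCResult:
    feature: str
    icc: float
    n_pairs: int
    model: str  # e.g. "ICC(1,1)"


def roc_auc(values, labels, feature: str = "") -> AUCResult:
    """Per-feature discrimination of the binary mutation label."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape:
        raise ParameterError("values and labels must have equal length")
    if not np.isfinite(v).all():
        raise ParameterError("values contain non-finite entries")
    pos, neg = v[y == 1], v[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ClassError(
            f"both classes required (n_pos={len(pos)}, n_neg={len(neg)})"
        )
    has_ties = len(np.unique(v)) < len(v)
    method = "exact" if (len(pos) * len(neg) <= _EXACT_LIMIT and not has_ties) else "asymptotic"
    res = mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    auc = float(res.statistic) / (len(pos) * len(neg))
    return AUCResult(
        feature=feature,
        auc=auc,
        p_two_sided=float(min(res.pvalue, 1.0)),
        direction=1 if auc >= 0.5 else -1,
        n_pos=len(pos),
        n_neg=len(neg),
        method=method,
    )


def correlation_matrix(table: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Symmetric inter-feature correlation matrix with unit diagonal.

    Constant columns have no defined correlation; those entries are reported
    as 0 with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ParameterError("method must be 'spearman' or 'pearson'")
    feats = table.drop(columns=["label"], errors="ignore")
    if len(feats) < 3:
        raise ParameterError("correlation matrix needs >= 3 subjects")
    corr = feats.corr(method=method)
    if corr.isna().any().any():
        constant = [c for c in feats.columns if feats[c].nunique() <= 1]
        warnings.warn(
            f"undefined correlations (constant columns {constant[:5]}) reported as 0",
            stacklevel=2,
        )
        corr = corr.fillna(0.0)
        np.fill_diagonal(corr.values, 1.0)
    return corr


_ICC_LABELS = {"icc1": "ICC(1,1)", "icc2": "ICC(2,1)", "icc3": "ICC(3,1)"}


def _icc_anova(t: np.ndarray, r: np.ndarray, model: str) -> float:
    """Single-measure ICC from the two-replicate ANOVA decomposition.

    Shrout-Fleiss forms with k = 2 raters: icc1 one-way random, icc2
    two-way random with absolute agreement, icc3 two-way mixed
    (consistency).
    """
    x = np.stack([t, r], axis=1)
    n, k = x.shape
    grand = x.mean()
    subj = x.mean(axis=1)
    rater = x.mean(axis=0)
    sst = ((x - grand) ** 2).sum()
    ssb = k * ((subj - grand) ** 2).sum()
    ssj = n * ((rater - grand) ** 2).sum()
    ssw = ((x - subj[:, None]) ** 2).sum()
    sse = sst - ssb - ssj
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    msj = ssj / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if model == "icc1":
        denom = msb + (k - 1) * msw
    elif model == "icc2":
        denom = msb + (k - 1) * mse + k * (msj - mse) / n
    else:
        denom = msb + (k - 1) * mse
    if denom <= 0:
        return float("nan")
    num = msb - (msw if model == "icc1" else mse)
    return float(num / denom)


def icc(test, retest, model: str = "icc1", feature: str = "") -> ICCResult:
    """Single-measurement intraclass correlation over paired replicates."""
    t = np.asarray(test, dtype=float)
    r = np.asarray(retest, dtype=float)
    if t.shape != r.shape:
        raise PairingError(f"test/retest length mismatch: {t.shape} vs {r.shape}")
    if t.ndim != 1 or len(t) < 2:
        raise PairingError("need >= 2 paired measurements")
    if model not in _ICC_LABELS:
        raise ParameterError(f"model must be one of {sorted(_ICC_LABELS)}")
    n = len(t)
    value = _icc_anova(t, r, model)
    return ICCResult(feature=feature, icc=value, n_pairs=n, model=_ICC_LABELS[model])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (supplementary output only)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
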