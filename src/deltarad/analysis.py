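"""Delta feature tables and variance/correlation feature selection.

A feature table is a pandas DataFrame of subjects x features with the
subject id as index, a ``label`` column (1 = sensitizing-mutant) and a
``timepoint`` tag in ``df.attrs`` ("pre", "post" or "delta"). The delta
table is pre-treatment minus post-treatment, cell-wise.

Selection follows the screening recipe: rank delta features by coefficient
of variation, keep the top k, then iteratively drop features until no
remaining pair is correlated above the threshold; Volume and Max_Diameter
are kept out of the ranking pool and appended for comparison.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import AlignmentError, ParameterError

LABEL_COLUMN = "label"
_ZERO_MEAN = 1e-12


def feature_columns(table: pd.DataFrame) -> List[str]:
    return [c for c in table.columns if c != LABEL_COLUMN]


def make_feature_table(
    rows: Iterable[dict], subject_ids: Sequence[str], labels: Sequence[int], timepoint: str
) -> pd.DataFrame:
    df = pd.DataFrame(list(rows), index=pd.Index(subject_ids, name="subject_id"))
    df.insert(0, LABEL_COLUMN, list(labels))
    df.attrs["timepoint"] = timepoint
    return df


def delta_table(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Cell-wise pre - post after aligning by subject id; labels must agree."""
    if set(pre.index) != set(post.index):
        raise AlignmentError(
            f"subject mismatch: {sorted(set(pre.index) ^ set(post.index))[:5]}"
        )
    post = post.loc[pre.index]
    cols_pre, cols_post = feature_columns(pre), feature_columns(post)
    if cols_pre != cols_post:
        raise AlignmentError(
            f"feature-column mismatch: {sorted(set(cols_pre) ^ set(cols_post))[:5]}"
        )
    if not (pre[LABEL_COLUMN] == post[LABEL_COLUMN]).all():
        raise AlignmentError("labels differ between pre and post tables")
    delta = pre[cols_pre] - post[cols_post]
    delta.insert(0, LABEL_COLUMN, pre[LABEL_COLUMN])
    delta.attrs["timepoint"] = "delta"
    return delta


def coefficient_of_variation(values) -> float:
    """Sample std over |mean|; NaN (excluded from ranking) for near-zero mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("coefficient of variation needs >= 2 values")
    mean = v.mean()
    if abs(mean) < _ZERO_MEAN:
        return float("nan")
    return float(v.std(ddof=1) / abs(mean))


class DeltaFeatureSelector(TransformerMixin, BaseEstimator):
    """CV-ranking + correlation-pruning feature selector (sklearn-compatible).

    Parameters
    ----------
    k : int
        Number of most-variant features (by coefficient of variation on the
        fitted table) kept before pruning.
    corr_threshold : float
        Pairs with |correlation| above this are considered redundant.
    method : {"spearman", "pearson"}
        Correlation statistic used for pruning.
    always_include : tuple of str
        Features excluded from the ranking pool and appended to the
        selection for comparison (the conventional size markers).

    Attributes
    ----------
    selected_features_ : list of str
    report_ : DataFrame with columns feature, cv, rank, pruned_by, selected.
    """

    def __init__(
        self,
        k: int = 15,
        corr_threshold: float = 0.95,
        method: str = "spearman",
        always_include: Tuple[str, ...] = ("Volume", "Max_Diameter"),
    ):
        self.k = k
        self.corr_threshold = corr_threshold
        self.method = method
        self.always_include = always_include

    def fit(self, X: pd.DataFrame, y=None):
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.method not in ("spearman", "pearson"):
            raise ParameterError("method must be 'spearman' or 'pearson'")
        X = X.drop(columns=[LABEL_COLUMN], errors="ignore")
        # deterministic regardless of incoming column order
        X = X[sorted(X.columns)]
        always = [f for f in self.always_include if f in X.columns]
        pool = [c for c in X.columns if c not in always]
        if self.k > len(pool):
            raise ParameterError(f"k={self.k} exceeds the {len(pool)}-feature pool")

        cv = {c: coefficient_of_variation(X[c].to_numpy()) for c in pool}
        ranked = sorted(
            (c for c in pool if np.isfinite(cv[c])),
            key=lambda c: (-cv[c], c),
        )
        top = ranked[: self.k]
        rank = {c: i + 1 for i, c in enumerate(ranked)}

        survivors, pruned_by = self._prune(X[top], cv)

        self.cv_ = cv
        self.selected_features_ = [c for c in top if c in survivors] + always
        rows = []
        for c in pool:
            selected = c in self.selected_features_
            rows.append(
                {
                    "feature": c,
                    "cv": cv[c],
                    "rank": rank.get(c, np.nan),
                    "pruned_by": pruned_by.get(c, ""),
                    "selected": selected,
                }
            )
        for c in always:
            rows.append(
                {"feature": c, "cv": np.nan, "rank": np.nan, "pruned_by": "", "selected": True}
            )
        self.report_ = pd.DataFrame(rows)
        return self

    def _prune(self, X: pd.DataFrame, cv: dict):
        """Drop features until no pair exceeds the correlation threshold.

        From the worst (most correlated) pair, the feature with the larger
        mean absolute correlation to the remaining candidates is removed;
        ties go to the lower CV, then to the lexicographically later name.
        """
        remaining = sorted(X.columns)
        pruned_by = {}
        if len(remaining) < 2:
            return set(remaining), pruned_by
        corr = X[remaining].corr(method=self.method).abs().fillna(0.0)
        while len(remaining) > 1:
            sub = corr.loc[remaining, remaining].to_numpy(copy=True)
            np.fill_diagonal(sub, 0.0)
            worst = sub.max()
            if worst <= self.corr_threshold:
                break
            a_i, b_i = np.unravel_index(int(sub.argmax()), sub.shape)
            a, b = remaining[a_i], remaining[b_i]

            def redundancy(f):
                others = [o for o in remaining if o != f]
                return float(corr.loc[f, others].mean())

            ra, rb = redundancy(a), redundancy(b)
            if ra != rb:
                drop = a if ra > rb else b
            elif cv.get(a, 0) != cv.get(b, 0):
                drop = a if cv.get(a, 0) < cv.get(b, 0) else b
            else:
                drop = max(a, b)
            keep = b if drop == a else a
            pruned_by[drop] = keep
            remaining.remove(drop)
        return set(remaining), pruned_by

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.selected_features_ if c not in X.columns]
        if missing:
            raise AlignmentError(f"table lacks selected features {missing[:5]}")
        return X[self.selected_features_]


def select_features(
    delta: pd.DataFrame,
    k: int = 15,
    corr_threshold: float = 0.95,
    method: str = "spearman",
    always_include: Tuple[str, ...] = ("Volume", "Max_Diameter"),
) -> List[str]:
    """Ordered selected feature names; thin wrapper over the transformer."""
    sel = DeltaFeatureSelector(
        k=k, corr_threshold=corr_threshold, method=method, always_include=always_include
    ).fit(delta)
    return sel.selected_features_
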