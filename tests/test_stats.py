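"""ROC AUC via Mann-Whitney, correlation matrices, and test-retest ICC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deltarad import correlation_matrix, icc, roc_auc
from deltarad.errors import ClassError, PairingError, ParameterError


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0 and r.direction == 1

    def test_printed_four_point_example(self):
        # values (1,2,3,4), labels (0,1,0,1): mutants win 3 of 4 pairs
        r = roc_auc([1, 2, 3, 4], [0, 1, 0, 1])
        assert r.auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        r = roc_auc([5.0] * 8, [0, 1] * 4)
        assert r.auc == pytest.approx(0.5)
        assert r.p_two_sided == pytest.approx(1.0, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ClassError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            v = rng.normal(size=30) + y
            assert roc_auc(v, y).auc == pytest.approx(roc_auc_score(y, v))

    def test_complement_symmetry(self, rng):
        y = np.array([0] * 10 + [1] * 12)
        v = rng.normal(size=22)
        assert roc_auc(v, y).auc + roc_auc(-v, y).auc == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50_000, 50_000), min_size=8, max_size=20, unique=True))
    def test_invariant_under_monotone_transform(self, values):
        y = np.arange(len(values)) % 2
        v = np.asarray(values, dtype=float) / 1000.0
        a = roc_auc(v, y).auc
        b = roc_auc(np.exp(v / 25.0), y).auc
        assert a == pytest.approx(b)

    def test_exact_and_asymptotic_p_agree(self, rng):
        from scipy.stats import mannwhitneyu

        for n_pos, n_neg in [(10, 10), (15, 15), (20, 20), (25, 20)]:
            y = np.array([1] * n_pos + [0] * n_neg)
            v = rng.permutation(np.arange(len(y), dtype=float))  # tie-free
            r = roc_auc(v, y)
            approx = mannwhitneyu(
                v[y == 1], v[y == 0], alternative="two-sided", method="asymptotic"
            ).pvalue
            expected = "exact" if n_pos * n_neg <= 400 else "asymptotic"
            assert r.method == expected
            if expected == "exact":
                assert abs(r.p_two_sided - approx) < 0.01


class TestCorrelationMatrix:
    def test_monotone_transform_gives_unit_spearman(self, rng):
        f = rng.normal(size=20)
        t = pd.DataFrame({"a": f, "b": np.exp(f)})
        corr = correlation_matrix(t, "spearman")
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        f = rng.normal(size=15)
        corr = correlation_matrix(pd.DataFrame({"a": f, "b": -f}), "spearman")
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_five_point_hand_ranked_spearman(self):
        # ranks of a: 1..5; ranks of b: 2 1 3 5 4 -> rho = 1 - 6*4/(5*24) = 0.8
        t = pd.DataFrame({"a": [10.0, 20, 30, 40, 50], "b": [1.1, 0.5, 2.0, 9.0, 7.0]})
        corr = correlation_matrix(t, "spearman")
        assert corr.loc["a", "b"] == pytest.approx(0.8)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        t = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        corr = correlation_matrix(t)
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert corr.abs().to_numpy().max() <= 1.0 + 1e-12

    def test_constant_column_reported_as_zero_with_warning(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=10), "c": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            corr = correlation_matrix(t)
        assert corr.loc["a", "c"] == 0.0
        assert corr.loc["c", "c"] == 1.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ParameterError):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2.0]}))


def _pingouin_icc(t, r, row):
    """Independent reference: pingouin's single-measure ICC table."""
    import pingouin as pg

    n = len(t)
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat([0, 1], n),
            "score": np.concatenate([np.asarray(t, float), np.asarray(r, float)]),
        }
    )
    return float(pg.intraclass_corr(long, "subject", "rater", "score")["ICC"].iloc[row])


class TestIcc:
    def test_identical_replicates_give_one(self):
        v = [1.0, 2.0, 5.0, 9.0]
        r = icc(v, v)
        assert r.icc == pytest.approx(1.0)
        assert r.model == "ICC(1,1)"

    def test_recovers_variance_ratio_of_generating_model(self, rng):
        sigma_b, sigma_e = 2.0, 1.0
        n = 200
        subject = rng.normal(0, sigma_b, n)
        t = subject + rng.normal(0, sigma_e, n)
        r = subject + rng.normal(0, sigma_e, n)
        target = sigma_b**2 / (sigma_b**2 + sigma_e**2)
        assert icc(t, r).icc == pytest.approx(target, abs=0.1)

    def test_independent_columns_give_near_zero(self, rng):
        t = rng.normal(size=200)
        r = rng.normal(size=200)
        assert abs(icc(t, r).icc) < 0.15

    @pytest.mark.parametrize("model,row", [("icc1", 0), ("icc2", 1), ("icc3", 2)])
    def test_matches_independent_reference_implementation(self, rng, model, row):
        for _ in range(3):
            base = rng.normal(size=30)
            t = base + rng.normal(0, 0.5, 30)
            r = base + rng.normal(0, 0.5, 30)
            assert icc(t, r, model=model).icc == pytest.approx(
                _pingouin_icc(t, r, row), abs=1e-8
            )

    def test_invariant_under_common_affine_transform(self, rng):
        base = rng.normal(size=40)
        t = base + rng.normal(0, 0.3, 40)
        r = base + rng.normal(0, 0.3, 40)
        assert icc(3.0 * t + 7.0, 3.0 * r + 7.0).icc == pytest.approx(icc(t, r).icc)

    def test_length_mismatch_rejected(self):
        with pytest.raises(PairingError):
            icc([1.0, 2.0], [1.0])

    def test_alternative_models_recorded(self, rng):
        base = rng.normal(size=20)
        t, r = base + rng.normal(0, 0.2, 20), base + rng.normal(0, 0.2, 20)
        assert icc(t, r, model="icc3").model == "ICC(3,1)"
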