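"""Redundancy filtering, factor analysis, scores and KMO."""

import numpy as np
import pandas as pd
import pytest

from thyropet import dimred


def make_planted_factor_data(n, loadings, seed=0):
    """Cases drawn from a planted orthogonal-factor model with unit variances."""
    rng = np.random.default_rng(seed)
    loadings = np.asarray(loadings, dtype=float)
    p, k = loadings.shape
    uniq = 1.0 - (loadings**2).sum(axis=1)
    factors = rng.standard_normal((n, k))
    noise = rng.standard_normal((n, p)) * np.sqrt(uniq)
    X = factors @ loadings.T + noise
    return pd.DataFrame(X, columns=[f"f{i:03d}" for i in range(p)])


class TestRedundancyFilter:
    def test_duplicated_column_keeps_exactly_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(40)
        frame = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.standard_normal(40)})
        retained = dimred.redundancy_filter(frame, threshold=0.9)
        assert sum(name in retained for name in ("a", "b")) == 1
        assert "c" in retained

    def test_orthogonal_features_all_retained(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.standard_normal((200, 6)), columns=list("abcdef"))
        assert len(dimred.redundancy_filter(frame, threshold=0.5)) == 6

    def test_retained_set_has_no_super_threshold_pair(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((60, 5))
        cols = {}
        for j in range(20):
            src = base[:, j % 5]
            cols[f"x{j:02d}"] = src + rng.standard_normal(60) * rng.uniform(0.05, 2.0)
        frame = pd.DataFrame(cols)
        retained = dimred.redundancy_filter(frame, threshold=0.9)
        corr = frame[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.9 + 1e-12  # exhaustive pair scan

    def test_constant_feature_removed_with_warning(self):
        frame = pd.DataFrame(
            {"const": np.ones(30), "x": np.random.default_rng(3).standard_normal(30)}
        )
        with pytest.warns(UserWarning, match="constant"):
            retained = dimred.redundancy_filter(frame)
        assert retained == ["x"]

    def test_deterministic_tie_break(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(50)
        frame = pd.DataFrame({"zz": a, "aa": a.copy()})
        assert dimred.redundancy_filter(frame) == dimred.redundancy_filter(frame.copy())


class TestFactorCountRule:
    @pytest.mark.parametrize("n,k", [(10, 1), (19, 1), (20, 2), (68, 6), (5, 1), (123, 12)])
    def test_one_factor_per_ten_subjects(self, n, k):
        assert dimred.n_factors_rule(n) == k


class TestFactorModel:
    def test_planted_two_factor_recovery(self):
        loadings = np.zeros((10, 2))
        loadings[:5, 0] = 0.8
        loadings[5:, 1] = 0.8
        frame = make_planted_factor_data(500, loadings, seed=5)
        model = dimred.fit_factor_model(frame, n_factors=2, prefiltered=True)
        got = model.loadings
        # align up to sign/permutation
        best = np.inf
        for perm in ([0, 1], [1, 0]):
            for s0 in (1, -1):
                for s1 in (1, -1):
                    cand = got[:, perm] * np.array([s0, s1])
                    best = min(best, np.abs(cand - loadings).max())
        assert best < 0.1

    def test_single_factor_dominates_common_variance(self):
        # heterogeneous loadings so varimax has a well-defined concentration
        loadings = np.linspace(0.45, 0.9, 8)[:, None]
        frame = make_planted_factor_data(400, loadings, seed=6)
        model = dimred.fit_factor_model(frame, n_factors=2, prefiltered=True)
        ssq = (model.loadings**2).sum(axis=0)
        assert ssq[0] / ssq.sum() > 0.9

    def test_varimax_preserves_communalities(self):
        rng = np.random.default_rng(7)
        loadings = rng.uniform(-0.7, 0.7, size=(12, 3))
        rotated = dimred._varimax(loadings)
        assert np.allclose(
            (loadings**2).sum(axis=1), (rotated**2).sum(axis=1), atol=1e-8
        )

    def test_more_factors_than_cases_rejected(self):
        frame = make_planted_factor_data(5, np.full((4, 1), 0.7))
        with pytest.raises(ValueError):
            dimred.fit_factor_model(frame, n_factors=6, prefiltered=True)


class TestProjection:
    @pytest.fixture
    def fitted(self):
        loadings = np.zeros((10, 2))
        loadings[:5, 0] = 0.75
        loadings[5:, 1] = 0.75
        frame = make_planted_factor_data(300, loadings, seed=8)
        model = dimred.fit_factor_model(frame, n_factors=2, prefiltered=True)
        return model, frame

    def test_train_score_covariance_matches_closed_form(self, fitted):
        model, frame = fitted
        scores = dimred.project_scores(model, frame)
        z = model.standardiser.transform(frame[model.retained_feature_names]).to_numpy()
        sample_corr = z.T @ z / len(z)
        w = model.score_weights
        expected = w.T @ sample_corr @ w  # regression-score shrinkage
        got = scores.T @ scores / len(scores)
        assert np.allclose(got, expected, atol=1e-6)

    def test_all_mean_case_zero_scores(self, fitted):
        model, frame = fitted
        mean_case = pd.DataFrame([frame.mean()], columns=frame.columns)
        assert np.allclose(dimred.project_scores(model, mean_case), 0.0, atol=1e-12)

    def test_permutation_permutes_rows_only(self, fitted):
        model, frame = fitted
        scores = dimred.project_scores(model, frame)
        perm = np.random.default_rng(9).permutation(len(frame))
        assert np.allclose(dimred.project_scores(model, frame.iloc[perm]), scores[perm])

    def test_missing_column_rejected(self, fitted):
        model, frame = fitted
        with pytest.raises(ValueError, match="missing"):
            dimred.project_scores(model, frame.drop(columns=[frame.columns[0]]))

    def test_test_cases_never_influence_fit(self):
        loadings = np.full((6, 1), 0.8)
        frame = make_planted_factor_data(120, loadings, seed=10)
        train = frame.iloc[:100]
        m1 = dimred.fit_factor_model(train, n_factors=1, prefiltered=True)
        m2 = dimred.fit_factor_model(train.copy(), n_factors=1, prefiltered=True)
        assert np.allclose(m1.loadings, m2.loadings, atol=1e-12)
        # projecting different test subsets uses identical weights
        s_all = dimred.project_scores(m1, frame.iloc[100:])
        s_sub = dimred.project_scores(m1, frame.iloc[100:110])
        assert np.allclose(s_all[:10], s_sub)


class TestKmo:
    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            frame = pd.DataFrame(rng.standard_normal((50, 6)))
            assert 0.0 <= dimred.compute_kmo(frame) <= 1.0

    def test_two_uncorrelated_features_near_half(self):
        # for p=2 the partial correlation equals the correlation, so KMO -> 0.5
        rng = np.random.default_rng(12)
        frame = pd.DataFrame(rng.standard_normal((5000, 2)), columns=["a", "b"])
        assert dimred.compute_kmo(frame) == pytest.approx(0.5, abs=0.01)

    def test_block_structured_data_high_kmo(self):
        # one strong common factor across all features -> high sampling adequacy
        loadings = np.full((12, 1), 0.9)
        frame = make_planted_factor_data(600, loadings, seed=13)
        assert dimred.compute_kmo(frame) > 0.8
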