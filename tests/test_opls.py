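import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from gutclpb.opls import (
    feature_correlations,
    fit_opls,
    permutation_validate,
    pqn_normalize,
    q2_cross_validate,
    uv_scale,
)
from gutclpb.synthetic import make_metabolome

from oracles import pqn_by_hand


class TestPqn:
    def test_matches_hand_computation_on_3x4_matrix(self):
        X = np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 4.0, 6.0, 8.0],
                [1.5, 2.5, 3.5, 5.0],
            ]
        )
        out, factors = pqn_normalize(X)
        assert np.allclose(out, pqn_by_hand(X))

    def test_dilution_series_collapses_to_common_spectrum(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 10, size=12)
        dilutions = np.array([0.5, 1.0, 2.0, 3.5, 8.0])
        X = np.outer(dilutions, base)
        out, factors = pqn_normalize(X)
        # all rows equal the base spectrum up to one global constant
        ratios = out / base
        assert np.allclose(ratios, ratios[0, 0])

    def test_idempotent_on_dilution_series(self):
        rng = np.random.default_rng(2)
        X = np.outer(rng.uniform(0.2, 5, 6), rng.uniform(1, 10, 9))
        once, _ = pqn_normalize(X)
        twice, factors = pqn_normalize(once)
        assert np.allclose(once, twice)
        assert np.allclose(factors, 1.0)

    def test_single_sample_unchanged(self):
        X = np.array([[1.0, 5.0, 2.0]])
        out, factors = pqn_normalize(X)
        assert np.allclose(out, X)
        assert factors[0] == 1.0

    def test_nonpositive_values_excluded_but_rescaled(self):
        X = np.array([[1.0, 2.0, -3.0, 4.0], [2.0, 4.0, -6.0, 8.0]])
        out, factors = pqn_normalize(X)
        assert np.allclose(out[:, 2] * factors, X[:, 2])  # rescaled, not dropped

    def test_sample_without_positive_features_named_in_error(self):
        X = pd.DataFrame(
            [[1.0, 2.0], [2.0, 4.0], [-1.0, -2.0]], index=["good1", "good2", "bad"]
        )
        with pytest.raises(ValueError, match="bad"):
            pqn_normalize(X)


class TestUvScale:
    def test_forced_example(self):
        out, scaler = uv_scale(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-1, 0, 1])

    def test_columns_centered_and_unit_sd(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 50, size=(20, 6))
        out, scaler = uv_scale(X)
        assert np.abs(out.mean(axis=0)).max() < 1e-12
        assert np.allclose(out.std(axis=0, ddof=1), 1.0)

    def test_round_trip_with_stored_params(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 50, size=(10, 4))
        out, scaler = uv_scale(X)
        assert np.allclose(scaler.inverse(out), X)

    def test_zero_variance_feature_listed_in_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            uv_scale(X)


class TestFitOpls:
    def test_noiseless_single_component_fit_is_exact(self):
        X, y, _ = make_metabolome(30, 10, n_ortho=0, noise_sd=0.0, seed=1)
        Xs, _ = uv_scale(X)
        model = fit_opls(Xs, y - y.mean(), n_ortho=0)
        assert model.r2y >= 0.999

    def test_orthogonal_filtering_improves_training_fit(self):
        X, y, _ = make_metabolome(40, 20, n_ortho=1, noise_sd=0.2, seed=2)
        Xs, _ = uv_scale(X)
        yc = y - y.mean()
        r2_plain = fit_opls(Xs, yc, n_ortho=0).r2y
        r2_ortho = fit_opls(Xs, yc, n_ortho=1).r2y
        assert r2_ortho >= r2_plain

    def test_orthogonality_invariants_hold_across_random_datasets(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n, m = int(rng.integers(10, 25)), int(rng.integers(4, 15))
            X = rng.standard_normal((n, m))
            y = rng.standard_normal(n)
            n_ortho = int(rng.integers(0, 3))
            model = fit_opls(X, y, n_ortho=n_ortho)
            assert np.isclose(np.linalg.norm(model.w), 1.0)
            assert np.abs(model.w @ model.W_o).max(initial=0.0) < 1e-8
            G = model.T_o.T @ model.T_o
            off = G - np.diag(np.diag(G))
            assert np.abs(off).max(initial=0.0) < 1e-8

    def test_plain_fit_equals_single_component_pls1(self):
        X, y, _ = make_metabolome(40, 15, n_ortho=0, noise_sd=0.3, seed=5)
        Xs, _ = uv_scale(X)
        yc = (y - y.mean()).to_numpy()
        model = fit_opls(Xs, yc, n_ortho=0)
        sk = PLSRegression(n_components=1, scale=False).fit(Xs.to_numpy(), yc)
        assert np.allclose(sk.predict(Xs.to_numpy()).ravel(), model.predict(Xs.to_numpy()))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_opls(np.zeros((10, 3)), np.arange(10.0))
        with pytest.raises(ValueError):
            fit_opls(np.random.default_rng(0).standard_normal((10, 3)), np.zeros(10))


class TestQ2:
    def test_noiseless_planted_data_recovered(self):
        X, y, _ = make_metabolome(42, 20, n_ortho=0, noise_sd=0.0, seed=6)
        assert q2_cross_validate(X, y, k=7, n_ortho=0) >= 0.95

    def test_q2_never_exceeds_one(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            X = rng.standard_normal((20, 8))
            y = rng.standard_normal(20)
            assert q2_cross_validate(X, y, k=4, n_ortho=1, seed=seed) <= 1.0

    def test_invariant_to_positive_scaling_of_y(self):
        X, y, _ = make_metabolome(30, 12, n_ortho=1, noise_sd=0.3, seed=8)
        a = q2_cross_validate(X, y, k=5, n_ortho=1)
        b = q2_cross_validate(X, 37.5 * y, k=5, n_ortho=1)
        assert a == pytest.approx(b, rel=1e-9)

    def test_permuted_response_scores_poorly(self):
        X, y, _ = make_metabolome(60, 40, n_ortho=1, noise_sd=0.1, seed=9)
        rng = np.random.default_rng(9)
        nulls = [
            q2_cross_validate(X, rng.permutation(y.to_numpy()), k=7, n_ortho=1)
            for _ in range(11)
        ]
        assert np.median(nulls) <= 0.2

    def test_fold_preconditions(self):
        X, y, _ = make_metabolome(10, 5, n_ortho=0, seed=1)
        with pytest.raises(ValueError):
            q2_cross_validate(X, y, k=7)  # n < 2k
        with pytest.raises(ValueError):
            q2_cross_validate(X, y, k=1)


class TestPermutation:
    def test_strong_signal_reaches_minimal_p(self):
        X, y, _ = make_metabolome(60, 40, n_ortho=1, noise_sd=0.1, seed=10)
        p, obs, null = permutation_validate(X, y, n_perm=99, seed=3)
        assert p == pytest.approx(1 / 100)
        assert obs > null.max()

    def test_add_one_formula(self):
        # a null as strong as any observed statistic cannot give p below 1/(n_perm+1)
        X, y, _ = make_metabolome(30, 10, n_ortho=0, noise_sd=0.2, seed=11)
        p, _, null = permutation_validate(X, y, n_perm=19, seed=4)
        count = int(round(p * 20 - 1))
        assert p == (1 + count) / 20
        assert 1 / 20 <= p <= 1.0


class TestFeatureCorrelations:
    def test_driver_itself_and_negated_driver(self):
        rng = np.random.default_rng(12)
        driver = rng.standard_normal(50)
        X = np.column_stack([driver, -driver, rng.standard_normal(50)])
        recs = feature_correlations(X, driver)
        assert recs[0].r == pytest.approx(1.0)
        assert recs[1].r == pytest.approx(-1.0)
        assert recs[0].q <= 1e-10

    def test_constant_feature_warns_with_null_record(self):
        rng = np.random.default_rng(13)
        X = np.column_stack([np.full(30, 7.0), rng.standard_normal(30)])
        with pytest.warns(UserWarning, match="constant"):
            recs = feature_correlations(X, rng.standard_normal(30))
        assert (recs[0].r, recs[0].p) == (0.0, 1.0)
        assert recs[0].q >= recs[0].p

    def test_planted_loadings_detected_and_nulls_controlled(self):
        rng = np.random.default_rng(14)
        n, n_signal, n_null = 200, 10, 30
        t = rng.standard_normal(n)
        loadings = rng.uniform(1, 2, n_signal)
        X = np.column_stack(
            [np.outer(t, loadings) + 0.3 * rng.standard_normal((n, n_signal)),
             rng.standard_normal((n, n_null))]
        )
        recs = feature_correlations(X, t)
        signal_q = [r.q for r in recs[:n_signal]]
        null_q = [r.q for r in recs[n_signal:]]
        assert all(q < 0.05 for q in signal_q)
        assert np.mean([q < 0.05 for q in null_q]) <= 0.10
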