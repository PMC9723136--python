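import numpy as np
import pytest
import scipy.optimize

from hyperbroad.bls import BlsConfig, BlsModel, bls_features, fit_bls, predict_bls
from hyperbroad.exceptions import FitError, ValidationError


def ridge_oracle(a: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Independent least-squares solve of the ridge system via the augmented
    design [A; sqrt(lam) I]."""
    d = a.shape[1]
    aug = np.vstack([a, np.sqrt(lam) * np.eye(d)])
    target = np.vstack([y, np.zeros((d, y.shape[1]))])
    return np.linalg.lstsq(aug, target, rcond=None)[0]


def small_fit(seed, n=30, d=10, cfg=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = np.array(["positive", "control"] * (n // 2))
    cfg = cfg or BlsConfig(n_map_groups=2, nodes_per_group=5, enh_nodes_per_group=4, ridge=1e-2)
    return X, y, fit_bls(X, y, cfg, seed=seed)


def test_identity_mapping_reproduces_input():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((6, 4))
    cfg = BlsConfig(
        n_map_groups=1, nodes_per_group=4, enh_nodes_per_group=2,
        map_activation="identity",
    )
    model = BlsModel(config=cfg, seed=0, input_dim=4)
    model.map_params = [(np.eye(4), np.zeros(4))]
    model.enh_params = [(np.zeros((4, 2)), np.zeros(2))]
    feats = bls_features(model, X)
    np.testing.assert_array_equal(feats[:, :4], X)


def test_zero_input_zero_bias_features_vanish():
    cfg = BlsConfig(n_map_groups=1, nodes_per_group=3, enh_nodes_per_group=2)
    model = BlsModel(config=cfg, seed=0, input_dim=5)
    model.map_params = [(np.ones((5, 3)), np.zeros(3))]
    model.enh_params = [(np.ones((3, 2)), np.zeros(2))]
    feats = bls_features(model, np.zeros((4, 5)))
    np.testing.assert_array_equal(feats, np.zeros((4, 5)))


def test_row_permutation_permutes_features():
    X, y, model = small_fit(1)
    perm = np.random.default_rng(2).permutation(len(X))
    np.testing.assert_array_equal(
        bls_features(model, X)[perm], bls_features(model, X[perm])
    )


def test_closed_form_matches_normal_equations_oracle():
    X, y, model = small_fit(3)
    a = bls_features(model, X)
    yh = np.zeros((len(y), 2))
    yh[y == "control", 0] = 1.0
    yh[y == "positive", 1] = 1.0
    expected = ridge_oracle(a, yh, model.config.ridge)
    np.testing.assert_allclose(model.W_out, expected, rtol=1e-8, atol=1e-10)


def test_closed_form_matches_convex_optimizer():
    X, y, model = small_fit(4)
    a = bls_features(model, X)
    yh = np.zeros((len(y), 2))
    yh[y == "control", 0] = 1.0
    yh[y == "positive", 1] = 1.0
    lam = model.config.ridge
    shape = model.W_out.shape

    def objective(w_flat):
        w = w_flat.reshape(shape)
        r = a @ w - yh
        return float(np.sum(r**2) + lam * np.sum(w**2))

    res = scipy.optimize.minimize(
        objective, np.zeros(shape).ravel(), method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
    )
    np.testing.assert_allclose(res.x.reshape(shape), model.W_out, atol=1e-5)


def test_strong_ridge_shrinks_weights():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((20, 6))
    y = np.array(["positive", "control"] * 10)
    lam = 1e8
    cfg = BlsConfig(n_map_groups=2, nodes_per_group=4, enh_nodes_per_group=2, ridge=lam)
    model = fit_bls(X, y, cfg, seed=0)
    a = bls_features(model, X)
    yh = np.zeros((20, 2))
    yh[y == "control", 0] = 1.0
    yh[y == "positive", 1] = 1.0
    bound = np.linalg.norm(a.T @ yh) / lam
    assert np.linalg.norm(model.W_out) <= bound + 1e-12


def test_training_error_monotone_in_ridge():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((25, 8))
    y = np.array(["positive", "control"] * 12 + ["positive"])
    cfg = BlsConfig(n_map_groups=2, nodes_per_group=6, enh_nodes_per_group=3, ridge=1.0)
    base = fit_bls(X, y, cfg, seed=1)  # fixes the random features
    a = bls_features(base, X)
    yh = np.zeros((25, 2))
    yh[y == "control", 0] = 1.0
    yh[y == "positive", 1] = 1.0
    errs = []
    for lam in (1e2, 1.0, 1e-2, 1e-4, 1e-6):
        w = np.linalg.solve(a.T @ a + lam * np.eye(a.shape[1]), a.T @ yh)
        errs.append(float(np.sum((a @ w - yh) ** 2)))
    assert all(b <= a_ + 1e-10 for a_, b in zip(errs[:-1], errs[1:]))


def test_extra_enhancement_group_never_hurts_training_residual():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((20, 5))
    y = np.array(["positive", "control"] * 10)
    lam = 1e-10
    small = fit_bls(X, y, BlsConfig(n_map_groups=2, nodes_per_group=4,
                                    n_enh_groups=1, enh_nodes_per_group=3, ridge=lam), seed=2)
    big = fit_bls(X, y, BlsConfig(n_map_groups=2, nodes_per_group=4,
                                  n_enh_groups=2, enh_nodes_per_group=3, ridge=lam), seed=2)
    yh = np.zeros((20, 2))
    yh[y == "control", 0] = 1.0
    yh[y == "positive", 1] = 1.0
    r_small = np.sum((bls_features(small, X) @ small.W_out - yh) ** 2)
    r_big = np.sum((bls_features(big, X) @ big.W_out - yh) ** 2)
    assert r_big <= r_small + 1e-8


def test_reproducible_from_seed():
    X, y, m1 = small_fit(8)
    _, _, m2 = small_fit(8)
    np.testing.assert_array_equal(m1.W_out, m2.W_out)


def test_separated_blobs_classified_perfectly():
    rng = np.random.default_rng(9)
    X = np.vstack([rng.normal(0, 0.1, (15, 4)), rng.normal(8, 0.1, (15, 4))])
    y = np.array(["control"] * 15 + ["positive"] * 15)
    model = fit_bls(X, y, BlsConfig(n_map_groups=3, nodes_per_group=10,
                                    enh_nodes_per_group=5, ridge=1e-6), seed=0)
    pred, scores = predict_bls(model, X)
    assert np.all(pred == y)
    # duplicating a row in the test batch duplicates its score row
    # (up to BLAS summation-order ulps)
    _, scores_dup = predict_bls(model, np.vstack([X, X[:1]]))
    np.testing.assert_allclose(scores_dup[-1], scores_dup[0], rtol=1e-10, atol=1e-14)


def test_interpolating_fit_scores_sum_to_one():
    rng = np.random.default_rng(10)
    X = rng.standard_normal((12, 40))  # overparameterized: nodes >> samples
    y = np.array(["positive", "control"] * 6)
    model = fit_bls(X, y, BlsConfig(n_map_groups=4, nodes_per_group=20,
                                    enh_nodes_per_group=10, ridge=1e-12), seed=0)
    _, scores = predict_bls(model, X)
    np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)


def test_single_class_and_bad_lambda_rejected():
    X = np.zeros((4, 3))
    with pytest.raises(FitError, match="single class"):
        fit_bls(np.random.default_rng(0).standard_normal((4, 3)),
                ["positive"] * 4, BlsConfig(), seed=0)
    with pytest.raises(ValidationError, match="lambda"):
        fit_bls(X, ["positive", "control", "positive", "control"],
                BlsConfig(ridge=0.0), seed=0)


def test_dimension_mismatch_rejected():
    X, y, model = small_fit(11)
    with pytest.raises(ValidationError, match="expected"):
        bls_features(model, np.zeros((3, 99)))
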