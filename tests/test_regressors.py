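import numpy as np
import pytest

from permvarsel import (
    Dataset,
    default_beta,
    fit_linreg,
    fit_rf,
    fit_sir,
    kernel_smooth,
    make_regressor,
    simulate_m1,
    simulate_m2,
    sir_direction,
)
from permvarsel.regressors import rule_of_thumb_bandwidth, sir_eigenvalues


# ---------------------------------------------------------------------------
# ordinary least squares


def test_ols_recovers_exact_linear_data():
    x = np.linspace(0, 5, 10)
    d = Dataset(x[:, None], 2.0 * x + 1.0)
    reg = fit_linreg(d)
    assert reg.intercept_ == pytest.approx(1.0)
    assert reg.coef_[0] == pytest.approx(2.0)
    assert np.mean((d.y - reg.predict(d.X)) ** 2) == pytest.approx(0.0, abs=1e-20)


def test_ols_constant_response_gives_flat_fit():
    rng = np.random.default_rng(0)
    d = Dataset(rng.normal(size=(20, 3)), np.full(20, 7.5))
    reg = fit_linreg(d)
    assert reg.intercept_ == pytest.approx(7.5)
    np.testing.assert_allclose(reg.coef_, 0.0, atol=1e-12)


def test_ols_matches_closed_form_simple_regression():
    # independent oracle: slope = Sxy/Sxx, intercept = ybar - slope * xbar
    x = np.array([0.0, 1.0, 2.0, 3.0])
    y = np.array([1.0, 3.0, 4.0, 8.0])
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    reg = fit_linreg(Dataset(x[:, None], y))
    assert reg.coef_[0] == pytest.approx(slope)
    assert reg.intercept_ == pytest.approx(intercept)


def test_ols_underdetermined_raises():
    with pytest.raises(ValueError, match="underdetermined"):
        fit_linreg(Dataset(np.ones((3, 3)), np.ones(3)))


def test_ols_rank_deficient_uses_minimum_norm(caplog):
    rng = np.random.default_rng(1)
    x = rng.normal(size=(20, 1))
    X = np.hstack([x, x])  # duplicated column
    d = Dataset(X, 3.0 * x[:, 0])
    with caplog.at_level("WARNING"):
        reg = fit_linreg(d)
    assert "minimum-norm" in caplog.text
    # minimum-norm splits the weight evenly across the duplicates
    np.testing.assert_allclose(reg.coef_, [1.5, 1.5], atol=1e-8)


def test_ols_residuals_orthogonal_to_design():
    rng = np.random.default_rng(7)
    for _ in range(5):
        X = rng.normal(size=(40, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=40)
        reg = fit_linreg(Dataset(X, y))
        r = y - reg.predict(X)
        design = np.column_stack([np.ones(40), X])
        scale = np.abs(design).max() * np.abs(r).max()
        assert np.max(np.abs(design.T @ r)) < 1e-8 * max(scale, 1.0)


# ---------------------------------------------------------------------------
# sliced inverse regression


def test_sir_direction_recovers_m1_index(m1_data):
    beta = default_beta()
    beta = beta / np.linalg.norm(beta)
    est = sir_direction(m1_data)
    assert abs(est @ beta) > 0.95


def test_sir_direction_unit_norm_and_sign(m1_data):
    est = sir_direction(m1_data)
    assert np.linalg.norm(est) == pytest.approx(1.0)
    assert est[np.argmax(np.abs(est))] > 0


def test_sir_direction_p1_trivial():
    d = Dataset(np.arange(30.0)[:, None], np.arange(30.0))
    np.testing.assert_array_equal(sir_direction(d), [1.0])


def test_sir_null_spectrum_is_flat_and_small():
    # Monte-Carlo calibration: with y independent of X the top eigenvalue of
    # the slice-mean covariance stays comparable to the rest (ratio < 5 in
    # >= 90% of seeds) and small in absolute terms, unlike the ~0.6+ top
    # eigenvalue (ratio > 10) that a real single-index signal produces.
    ratios, tops = [], []
    for s in range(100):
        rng = np.random.default_rng(s)
        d = Dataset(rng.normal(size=(200, 5)), rng.normal(size=200))
        e = sir_eigenvalues(d)
        ratios.append(e[-1] / e[:-1].mean())
        tops.append(e[-1])
    assert np.mean(np.asarray(ratios) < 5.0) >= 0.90
    assert np.median(tops) < 0.2


def test_sir_direction_invariant_to_column_rescaling(m1_data):
    est = sir_direction(m1_data)
    X2 = m1_data.X.copy()
    X2[:, 2] *= 10.0
    est2 = sir_direction(Dataset(X2, m1_data.y, m1_data.names))
    # index X'beta is preserved when the rescaled coefficient is mapped back
    back = est2.copy()
    back[2] *= 10.0
    back /= np.linalg.norm(back)
    assert abs(back @ est) > 0.999


def test_sir_requires_enough_observations_per_slice():
    d = Dataset(np.random.default_rng(0).normal(size=(12, 3)), np.arange(12.0))
    with pytest.raises(ValueError, match="2\\*n_slices"):
        sir_direction(d, n_slices=10)


# ---------------------------------------------------------------------------
# kernel smoothing


def test_kernel_smooth_constant_response():
    out = kernel_smooth(np.arange(5.0), np.full(5, 3.3), np.linspace(-2, 6, 9), 0.7)
    np.testing.assert_allclose(out, 3.3)


def test_kernel_smooth_single_training_point():
    out = kernel_smooth([2.0], [5.0], [0.0, 2.0, 10.0], 1.0)
    np.testing.assert_allclose(out, 5.0)


def test_kernel_smooth_matches_three_term_hand_calculation():
    # q=1, t=(0,1,2), h=0.5: weights exp(-2), exp(0), exp(-2)
    w = np.exp([-2.0, 0.0, -2.0])
    expected = np.sum(w * [0.0, 1.0, 4.0]) / np.sum(w)
    out = kernel_smooth([0.0, 1.0, 2.0], [0.0, 1.0, 4.0], [1.0], 0.5)
    assert out[0] == pytest.approx(expected)


def test_kernel_smooth_predictions_within_response_range():
    rng = np.random.default_rng(5)
    t = rng.normal(size=50)
    y = rng.normal(size=50)
    q = rng.normal(scale=3.0, size=200)
    for h in (0.05, 0.5, 5.0):
        out = kernel_smooth(t, y, q, h)
        assert out.min() >= y.min() - 1e-12
        assert out.max() <= y.max() + 1e-12


def test_kernel_smooth_far_query_returns_nearest_response():
    t = np.array([0.0, 1.0])
    y = np.array([-1.0, 4.0])
    out = kernel_smooth(t, y, [1e6], 0.1)  # all raw weights underflow
    assert out[0] == pytest.approx(4.0)


def test_kernel_smooth_input_validation():
    with pytest.raises(ValueError, match="bandwidth"):
        kernel_smooth([0.0], [1.0], [0.0], 0.0)
    with pytest.raises(ValueError, match="equal length"):
        kernel_smooth([0.0, 1.0], [1.0], [0.0], 1.0)


def test_bandwidth_rule_of_thumb():
    t = np.random.default_rng(0).normal(size=100)
    assert rule_of_thumb_bandwidth(t) == pytest.approx(
        1.06 * np.std(t) * 100 ** (-0.2)
    )
    assert rule_of_thumb_bandwidth(np.ones(10)) == 1.0  # degenerate index


# ---------------------------------------------------------------------------
# single-index fit and forest


def test_fit_sir_noiseless_m1_tracks_response():
    d = simulate_m1(seed=4, noise_sd=0.0)
    reg = fit_sir(d)
    preds = reg.predict(d.X)
    assert np.corrcoef(preds, d.y)[0, 1] > 0.99


def test_fit_sir_beats_linreg_on_cubic_link(m2_data):
    sir_mse = np.mean((m2_data.y - fit_sir(m2_data).predict(m2_data.X)) ** 2)
    lin_mse = np.mean((m2_data.y - fit_linreg(m2_data).predict(m2_data.X)) ** 2)
    assert sir_mse < lin_mse


def test_fit_sir_constant_response():
    rng = np.random.default_rng(2)
    d = Dataset(rng.normal(size=(40, 3)), np.full(40, 2.0))
    np.testing.assert_allclose(fit_sir(d).predict(d.X), 2.0)


def test_forest_constant_response():
    rng = np.random.default_rng(3)
    d = Dataset(rng.normal(size=(30, 2)), np.full(30, -1.5))
    np.testing.assert_allclose(fit_rf(d, n_trees=20, seed=0).predict(d.X), -1.5)


def test_forest_seeded_determinism():
    rng = np.random.default_rng(4)
    d = Dataset(rng.normal(size=(60, 3)), rng.normal(size=60))
    p1 = fit_rf(d, n_trees=30, seed=9).predict(d.X)
    p2 = fit_rf(d, n_trees=30, seed=9).predict(d.X)
    np.testing.assert_array_equal(p1, p2)


def test_forest_learns_step_function():
    rng = np.random.default_rng(6)
    X = rng.uniform(size=(300, 3))
    y = np.where(X[:, 0] > 0.5, 5.0, -5.0) + rng.normal(scale=0.3, size=300)
    train, test = Dataset(X[:150], y[:150]), Dataset(X[150:], y[150:])
    mse = np.mean((test.y - fit_rf(train, n_trees=100, seed=0).predict(test.X)) ** 2)
    assert mse < 0.2 * np.var(y)


def test_predict_before_fit_refuses():
    reg = make_regressor("linreg")
    with pytest.raises(RuntimeError, match="fitted"):
        reg.predict(np.ones((2, 2)))


def test_unknown_method_lists_valid_ones():
    with pytest.raises(ValueError, match="linreg"):
        make_regressor("lasso")


@pytest.mark.parametrize("kind,kw", [("linreg", {}), ("sir", {}), ("rf", {"n_trees": 30})])
def test_shuffled_response_gives_variance_level_error(kind, kw):
    # destroying the X-y link leaves only Var(y) to predict: averaged over
    # seeds, held-out MSE of any method sits near the response variance
    rng = np.random.default_rng(11)
    ratios = []
    for _ in range(50):
        X = rng.uniform(0.0, 0.7, size=(100, 4))
        y = X @ np.array([3.0, -2.0, 1.0, 0.0]) + rng.normal(size=100)
        y = rng.permutation(y)
        train = Dataset(X[:70], y[:70])
        reg = make_regressor(kind, **kw).fit(train)
        mse = np.mean((y[70:] - reg.predict(X[70:])) ** 2)
        ratios.append(mse / np.var(y))
    assert abs(np.mean(ratios) - 1.0) < 0.25
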