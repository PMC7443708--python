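"""Spatial binomial parent model: fit, draws, and covariance behaviour."""

import numpy as np
import pytest
from scipy.special import expit

from washmap.spatial import DrawCube, FitError, GeostatConfig, fit_parent


def _simulate(seed=0, n_clusters=120, trials=20, slope=1.0, n_cells=49, n_years=4):
    """Binomial clusters from a no-field truth with one informative feature."""
    rng = np.random.default_rng(seed)
    side = int(np.sqrt(n_cells))
    coords = np.array([[i // side, i % side] for i in range(n_cells)], float)
    years = tuple(range(2000, 2000 + n_years))
    cells = rng.integers(0, n_cells, n_clusters)
    obs_years = rng.choice(years, n_clusters)
    x = rng.normal(0, 1, n_clusters)
    s = rng.binomial(trials, expit(-0.3 + slope * x))
    X = np.column_stack([np.ones(n_clusters), x])
    return coords, years, X, s, np.full(n_clusters, trials), cells, obs_years


@pytest.fixture(scope="module")
def fitted():
    coords, years, X, s, t, cells, obs_years = _simulate(seed=1)
    post = fit_parent(coords, years, X, s, t, cells, obs_years,
                      GeostatConfig(seed=2, max_opt_evals=40))
    return post, coords, years


def test_cube_shape_and_range(fitted):
    post, coords, years = fitted
    Xp = np.dstack([np.ones((len(coords), len(years))),
                    np.zeros((len(coords), len(years)))])
    cube = post.sample_surface(n_draws=50, X_pred=Xp)
    assert cube.values.shape == (len(coords), len(years), 50)
    assert np.all(cube.values > 0) and np.all(cube.values < 1)
    # point estimate = mean over draws
    assert np.allclose(cube.mean(), cube.values.mean(axis=2))


def test_draws_seeded_determinism(fitted):
    post, coords, years = fitted
    Xp = np.dstack([np.ones((len(coords), len(years))),
                    np.zeros((len(coords), len(years)))])
    a = post.sample_surface(n_draws=30, X_pred=Xp, seed=5)
    b = post.sample_surface(n_draws=30, X_pred=Xp, seed=5)
    assert np.array_equal(a.values, b.values)
    c = post.sample_surface(n_draws=30, X_pred=Xp, seed=6)
    assert not np.array_equal(a.values, c.values)


def test_draw_limit_enforced(fitted):
    post, coords, years = fitted
    with pytest.raises(ValueError, match="exceeds configured maximum"):
        post.sample_surface(n_draws=10_000)


def test_mean_monotone_in_feature(fitted):
    """With beta > 0 and the random effects zeroed, the posterior-mean
    surface increases with the stacked feature (link monotonicity)."""
    post, coords, years = fitted
    beta = post.mode[: post.p]
    assert beta[1] > 0
    grid = np.linspace(-2, 2, 9)
    eta = beta[0] + beta[1] * grid
    assert np.all(np.diff(expit(eta)) > 0)


def test_slope_recovery_two_seeds():
    """95% interval for the slope covers the truth (quick two-seed check;
    the 20-seed version runs in the acceptance suite)."""
    for seed in (3, 4):
        coords, years, X, s, t, cells, obs_years = _simulate(seed=seed)
        post = fit_parent(coords, years, X, s, t, cells, obs_years,
                          GeostatConfig(seed=seed, max_opt_evals=40))
        draws = post._draw_latent(400, np.random.default_rng(seed))[:, 1]
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo <= 1.0 <= hi


def test_spatial_correlation_decays_with_distance():
    """Draws from a fit to data generated with range >> cell size show higher
    across-draw correlation between nearby cells than between far cells."""
    rng = np.random.default_rng(7)
    from washmap.synthetic import spatial_chol

    n_cells, n_years, trials = 64, 3, 40
    side = 8
    coords = np.array([[i // side, i % side] for i in range(n_cells)], float)
    years = (2000, 2001, 2002)
    Ls = spatial_chol(coords, 5.0)
    field = 1.2 * (Ls @ rng.standard_normal(n_cells))
    cells = np.tile(np.arange(n_cells), n_years)
    obs_years = np.repeat(years, n_cells)
    p = expit(field[cells])
    s = rng.binomial(trials, p)
    X = np.ones((len(cells), 1))
    post = fit_parent(coords, years, X, s, np.full(len(cells), trials),
                      cells, obs_years, GeostatConfig(seed=8, max_opt_evals=40))
    cube = post.sample_surface(n_draws=250, X_pred=np.ones((n_cells, n_years, 1)))
    draws = np.log(cube.values / (1 - cube.values))[:, 0, :]  # year 2000 logits
    near = np.corrcoef(draws[0], draws[1])[0, 1]       # distance 1
    far = np.corrcoef(draws[0], draws[63])[0, 1]       # distance ~9.9
    assert near > far


def test_nonfinite_features_rejected():
    coords, years, X, s, t, cells, obs_years = _simulate(seed=9)
    X[0, 0] = np.inf
    with pytest.raises(ValueError, match="finite"):
        fit_parent(coords, years, X, s, t, cells, obs_years, GeostatConfig())


def test_unfitted_posterior_refuses_to_sample():
    from washmap.spatial import ParentPosterior

    coords, years, X, s, t, cells, obs_years = _simulate(seed=10)
    post = ParentPosterior(coords, years, X, s, t, cells, obs_years, GeostatConfig())
    with pytest.raises(FitError):
        post.sample_surface(n_draws=10)


def test_drawcube_roundtrip(tmp_path, fitted):
    post, coords, years = fitted
    Xp = np.dstack([np.ones((len(coords), len(years))),
                    np.zeros((len(coords), len(years)))])
    cube = post.sample_surface(n_draws=20, X_pred=Xp)
    cube.indicator = "conditional"
    cube.conditional_level = 2
    cube.save(tmp_path / "cube")
    back = DrawCube.load(tmp_path / "cube")
    assert np.array_equal(back.values, cube.values)
    assert back.years == cube.years and back.conditional_level == 2


def test_mcmc_backend_same_contract():
    coords, years, X, s, t, cells, obs_years = _simulate(seed=11, n_clusters=60)
    post = fit_parent(
        coords, years, X, s, t, cells, obs_years,
        GeostatConfig(seed=12, inference="mcmc", estimate_hyperparams=False,
                      n_draws=50, mcmc_steps=400),
    )
    assert 0.05 < post.mcmc_accept < 0.9
    Xp = np.dstack([np.ones((len(coords), len(years))),
                    np.zeros((len(coords), len(years)))])
    cube = post.sample_surface(n_draws=50, X_pred=Xp)
    assert cube.values.shape == (len(coords), len(years), 50)
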