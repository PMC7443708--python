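"""Stacked-ensemble child models and fold bookkeeping."""

import numpy as np
import pytest
from scipy.special import expit

from washmap.stacking import (
    ChildModelSpec,
    _L1Logistic,
    assign_folds,
    build_features,
    default_specs,
    fit_children,
    predict_child_rasters,
)


def _null_dataset(n=400, trials=5, rate=0.3, seed=0):
    """Outcome independent of covariates."""
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [rng.normal(size=(n, 3)), rng.integers(0, 10, (n, 2)).astype(float),
         rng.choice(np.arange(2000, 2006), n).astype(float)]
    )
    s = rng.binomial(trials, rate, size=n)
    return X, s, np.full(n, trials), np.arange(n)


def test_null_signal_children_predict_pooled_rate():
    """With no covariate signal (pooled rate 0.3, n=2000 households), every
    child's mean out-of-sample prediction stays near the pooled rate."""
    X, s, t, g = _null_dataset(n=400, trials=5, rate=0.3, seed=1)
    sf = fit_children(X, s, t, g, seed=2)
    for j, learner in enumerate(sf.learners):
        assert 0.27 <= sf.oos_probs[:, j].mean() <= 0.33, learner


def test_l1_infinite_penalty_gives_pooled_rate():
    """C -> 0 shrinks all coefficients to zero; the unpenalised intercept
    leaves exactly the pooled empirical rate."""
    X, s, t, g = _null_dataset(n=300, trials=8, rate=0.4, seed=3)
    model = _L1Logistic(fixed_C=1e-8, seed=0).fit(X, s, t)
    pooled = s.sum() / t.sum()
    assert np.allclose(model.predict(X), pooled, atol=0.01)


def test_degenerate_outcome_warns_and_returns_clipped_rate():
    X, _, t, g = _null_dataset(n=50, trials=4, seed=4)
    s = np.zeros(50, int)
    with pytest.warns(UserWarning, match="degenerate"):
        sf = fit_children(X, s, t, g, seed=0)
    assert np.allclose(sf.oos_probs, 1e-4)


def test_fold_bookkeeping_no_self_prediction():
    """Each observation's stacked feature must come from children fitted on
    the other folds: recomputing the lasso child on a fold's complement
    reproduces the reported out-of-sample prediction."""
    X, s, t, g = _null_dataset(n=200, trials=6, seed=5)
    rng = np.random.default_rng(6)
    beta = np.zeros(X.shape[1]); beta[0] = 2.0
    s = rng.binomial(t, expit(-0.5 + X @ beta))
    spec = ChildModelSpec("l1_logistic", {"fixed_C": 1.0}, n_folds=5, seed=9)
    sf = fit_children(X, s, t, g, specs=[spec], seed=9)
    f = sf.fold_labels
    for fold in range(5):
        tr, te = f != fold, f == fold
        refit = _L1Logistic(fixed_C=1.0, seed=9).fit(X[tr], s[tr], t[tr])
        assert np.allclose(sf.oos_probs[te, 0], refit.predict(X[te]))


def test_assign_folds_partitions_groups():
    groups = np.repeat(np.arange(20), 3)
    folds = assign_folds(groups, 5, seed=0)
    assert set(folds) == set(range(5))
    # all members of a group share a fold
    for gid in range(20):
        assert len(set(folds[groups == gid])) == 1
    with pytest.raises(ValueError):
        assign_folds(np.arange(3), 5, seed=0)


def test_informative_covariate_beats_null_brier():
    """A strongly informative covariate (logit slope 2) should give every
    child a better out-of-sample Brier score than the null model."""
    wins = np.zeros(3)
    n_seeds = 6
    for seed in range(n_seeds):
        rng = np.random.default_rng(100 + seed)
        n, trials = 300, 5
        X = np.column_stack(
            [rng.normal(size=n), rng.integers(0, 10, (n, 2)).astype(float),
             np.full(n, 2003.0)]
        )
        p = expit(2.0 * X[:, 0])
        s = rng.binomial(trials, p)
        t = np.full(n, trials)
        sf = fit_children(X, s, t, np.arange(n), seed=seed)
        obs = s / t
        null_brier = np.mean((obs - obs.mean()) ** 2)
        briers = np.mean((sf.oos_probs - obs[:, None]) ** 2, axis=0)
        wins += briers < null_brier
    assert np.all(wins >= n_seeds - 1)


def test_predict_child_rasters_contract():
    X, s, t, g = _null_dataset(n=200, trials=6, seed=7)
    sf = fit_children(X, s, t, g, seed=8)
    covs = np.random.default_rng(0).normal(size=(3, 25))
    coords = np.array([[i // 5, i % 5] for i in range(25)], float)
    r = predict_child_rasters(sf, covs, coords, [2000, 2001])
    assert r.shape == (3, 25, 2)
    assert np.all(r >= 1e-4) and np.all(r <= 1 - 1e-4)
    r2 = predict_child_rasters(sf, covs, coords, [2000, 2001])
    assert np.array_equal(r, r2)
    with pytest.raises(ValueError, match="missing covariate"):
        bad = covs.copy(); bad[0, 0] = np.nan
        predict_child_rasters(sf, bad, coords, [2000])


def test_boosted_trees_seeded_refit_identical():
    X, s, t, g = _null_dataset(n=250, trials=6, seed=9)
    spec = [ChildModelSpec("boosted_trees", n_folds=5, seed=13)]
    a = fit_children(X, s, t, g, specs=spec, seed=13)
    b = fit_children(X, s, t, g, specs=spec, seed=13)
    assert np.array_equal(a.oos_probs, b.oos_probs)
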