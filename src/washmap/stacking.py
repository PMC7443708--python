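"""Stacked-generalisation child models.

Three child learners are fitted to each conditional binomial dataset — an
additive smoother (penalised-spline GAM), boosted regression trees, and
L1-penalised (lasso) logistic regression — and their cross-validated
out-of-sample predictions become covariates for the spatial parent model.
K-fold stacking guarantees no observation is ever predicted by a model
trained on its own fold; full-data refits provide the per-cell/year child
prediction rasters.

Child features are the gridded covariates plus cell row, column, and calendar
year.  Predicted probabilities are clipped to ``[1e-4, 1 - 1e-4]`` before any
logit transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from washmap._rng import child_rng, child_seed

PROB_CLIP = (1e-4, 1.0 - 1e-4)
LEARNERS = ("additive_smoother", "boosted_trees", "l1_logistic")


def clip_probs(p: np.ndarray) -> np.ndarray:
    return np.clip(p, *PROB_CLIP)


def logit(p: np.ndarray) -> np.ndarray:
    p = clip_probs(p)
    return np.log(p / (1.0 - p))


@dataclass
class ChildModelSpec:
    learner: str
    hyperparameters: dict = field(default_factory=dict)
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"learner must be one of {LEARNERS}")


def default_specs(seed: int = 0, n_folds: int = 5) -> list[ChildModelSpec]:
    return [ChildModelSpec(l, n_folds=n_folds, seed=seed) for l in LEARNERS]


# --------------------------------------------------------------------------
# individual learners.  Each takes (X, successes, trials) with X columns
# [cov..., row, col, year] and returns a predict(X)->prob callable.


def _degenerate_rate(successes: np.ndarray, trials: np.ndarray) -> float | None:
    s, n = successes.sum(), trials.sum()
    if s == 0 or s == n:
        return float(np.clip(s / n, *PROB_CLIP))
    return None


class _ConstantModel:
    def __init__(self, rate: float):
        self.rate = rate

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.rate)


class _AdditiveSmoother:
    """Binomial GAM: penalised B-splines on row and col (a smooth spatial
    surface, additively) plus linear covariate and year terms.  The penalty
    weight is selected by a small k-fold deviance grid."""

    def __init__(self, alpha_grid=(0.1, 1.0, 10.0), spline_df=6, cv_folds=3, seed=0):
        self.alpha_grid = alpha_grid
        self.spline_df = spline_df
        self.cv_folds = cv_folds
        self.seed = seed

    def _design(self, X: np.ndarray):
        # last three columns are row, col, year
        return X[:, -3:-1], np.column_stack([np.ones(len(X)), X[:, :-3], X[:, -1]])

    def fit(self, X, successes, trials):
        from statsmodels.gam.api import BSplines, GLMGam
        import statsmodels.api as sm

        rate = _degenerate_rate(successes, trials)
        if rate is not None:
            warnings.warn("degenerate outcome; additive smoother returns pooled rate")
            return _ConstantModel(rate)
        smooth_x, exog = self._design(X)
        df = min(self.spline_df, max(4, len(np.unique(smooth_x[:, 0]))))
        df2 = min(self.spline_df, max(4, len(np.unique(smooth_x[:, 1]))))
        self._bs = BSplines(smooth_x, df=[df, df2], degree=[3, 3])
        # B-spline bases cannot extrapolate: clamp later predictions to the
        # training range (constant extension beyond the outermost knots)
        self._smooth_lo = smooth_x.min(axis=0)
        self._smooth_hi = smooth_x.max(axis=0)
        endog = np.column_stack([successes, trials - successes])
        alpha = self._select_alpha(endog, exog, smooth_x)
        model = GLMGam(
            endog, exog=exog, smoother=self._bs, alpha=alpha,
            family=sm.families.Binomial(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._res = model.fit(maxiter=100)
        self._exog_builder = self._design
        return self

    def _select_alpha(self, endog, exog, smooth_x):
        import statsmodels.api as sm
        from statsmodels.gam.api import BSplines, GLMGam

        if len(self.alpha_grid) == 1:
            return [self.alpha_grid[0]] * 2
        n = len(endog)
        rng = child_rng(self.seed, "gam.alpha")
        folds = rng.integers(0, self.cv_folds, size=n)
        df = [s.df for s in self._bs.smoothers]
        best, best_dev = None, np.inf
        for a in self.alpha_grid:
            dev = 0.0
            ok = True
            for f in range(self.cv_folds):
                tr = folds != f
                if tr.all() or not tr.any():
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        bs_f = BSplines(smooth_x[tr], df=df, degree=[3, 3])
                        res = GLMGam(
                            endog[tr], exog=exog[tr], smoother=bs_f, alpha=[a, a],
                            family=sm.families.Binomial(),
                        ).fit(maxiter=50)
                        # held-out binomial deviance (clamped to fold knots)
                        held = np.clip(
                            smooth_x[~tr], smooth_x[tr].min(0), smooth_x[tr].max(0)
                        )
                        basis = bs_f.transform(held)
                        eta = exog[~tr] @ res.params[: exog.shape[1]] + basis @ res.params[exog.shape[1]:]
                        p = clip_probs(1.0 / (1.0 + np.exp(-eta)))
                        s = endog[~tr][:, 0]
                        m = endog[~tr].sum(axis=1)
                        dev -= float(np.sum(s * np.log(p) + (m - s) * np.log(1 - p)))
                except Exception:
                    ok = False
                    break
            if ok and dev < best_dev:
                best, best_dev = a, dev
        return [best if best is not None else 1.0] * 2

    def predict(self, X: np.ndarray) -> np.ndarray:
        if isinstance(self, _ConstantModel):  # pragma: no cover
            return self.predict(X)
        smooth_x, exog = self._design(X)
        smooth_x = np.clip(smooth_x, self._smooth_lo, self._smooth_hi)
        basis = self._bs.transform(smooth_x)
        k = exog.shape[1]
        eta = exog @ self._res.params[:k] + basis @ self._res.params[k:]
        return clip_probs(1.0 / (1.0 + np.exp(-eta)))


class _BoostedTrees:
    """LightGBM gradient-boosted trees on the cross-entropy objective, with
    fractional labels weighted by trials.  Depth 3, learning rate 0.1, up to
    500 rounds with early stopping on an internal 20% split."""

    def __init__(self, max_depth=3, learning_rate=0.1, max_rounds=500, seed=0):
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.max_rounds = max_rounds
        self.seed = seed

    def fit(self, X, successes, trials):
        import lightgbm as lgb

        rate = _degenerate_rate(successes, trials)
        if rate is not None:
            warnings.warn("degenerate outcome; boosted trees return pooled rate")
            return _ConstantModel(rate)
        y = successes / trials
        rng = child_rng(self.seed, "lgb.split")
        val = rng.random(len(y)) < 0.2
        if val.all() or not val.any():
            val = np.zeros(len(y), bool)
            val[: max(1, len(y) // 5)] = True
        params = dict(
            objective="cross_entropy",
            max_depth=self.max_depth,
            num_leaves=2**self.max_depth,
            learning_rate=self.learning_rate,
            min_child_samples=5,
            num_threads=1,
            deterministic=True,
            force_row_wise=True,
            seed=child_seed(self.seed, "lgb"),
            verbosity=-1,
        )
        dtrain = lgb.Dataset(X[~val], label=y[~val], weight=trials[~val])
        dval = lgb.Dataset(X[val], label=y[val], weight=trials[val], reference=dtrain)
        self._booster = lgb.train(
            params,
            dtrain,
            num_boost_round=self.max_rounds,
            valid_sets=[dval],
            callbacks=[lgb.early_stopping(25, verbose=False)],
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return clip_probs(self._booster.predict(X, num_iteration=self._booster.best_iteration))


class _L1Logistic:
    """Lasso logistic regression on standardised features; the penalty is
    selected by cross-validation.  The intercept is unpenalised, so in the
    infinite-penalty limit predictions collapse to the pooled rate."""

    def __init__(self, Cs=None, cv=3, seed=0, fixed_C=None):
        self.Cs = Cs if Cs is not None else np.logspace(-2, 2, 5)
        self.cv = cv
        self.seed = seed
        self.fixed_C = fixed_C

    def fit(self, X, successes, trials):
        from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
        from sklearn.preprocessing import StandardScaler

        rate = _degenerate_rate(successes, trials)
        if rate is not None:
            warnings.warn("degenerate outcome; lasso returns pooled rate")
            return _ConstantModel(rate)
        # expand each binomial obs into a success row and a failure row
        Xd = np.repeat(X, 2, axis=0)
        yd = np.tile([1.0, 0.0], len(X))
        wd = np.column_stack([successes, trials - successes]).reshape(-1).astype(float)
        keep = wd > 0
        self._scaler = StandardScaler().fit(X)
        Xs = self._scaler.transform(Xd[keep])
        if self.fixed_C is not None:
            self._clf = LogisticRegression(
                penalty="l1", solver="saga", max_iter=3000, tol=1e-7,
                C=self.fixed_C, random_state=child_seed(self.seed, "l1"),
            )
        else:
            # coarser tolerance: this path only selects the penalty
            self._clf = LogisticRegressionCV(
                penalty="l1", solver="saga", max_iter=800, tol=1e-4,
                Cs=self.Cs, cv=self.cv, random_state=child_seed(self.seed, "l1"),
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._clf.fit(Xs, yd[keep], sample_weight=wd[keep])
        if not np.any(self._clf.coef_):
            # analytic infinite-penalty limit: intercept-only model equals
            # the (clipped) pooled rate
            return _ConstantModel(float(np.clip(successes.sum() / trials.sum(), *PROB_CLIP)))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return clip_probs(self._clf.predict_proba(self._scaler.transform(X))[:, 1])


def _make_learner(spec: ChildModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.learner == "additive_smoother":
        return _AdditiveSmoother(seed=spec.seed, **hp)
    if spec.learner == "boosted_trees":
        return _BoostedTrees(seed=spec.seed, **hp)
    return _L1Logistic(seed=spec.seed, **hp)


def _tune_spec(spec: ChildModelSpec, X, successes, trials) -> ChildModelSpec:
    """Select data-driven hyperparameters once on the full data and freeze
    them, so fold refits share the selection instead of re-running it."""
    hp = dict(spec.hyperparameters)
    if spec.learner == "additive_smoother" and "alpha_grid" not in hp:
        learner = _AdditiveSmoother(seed=spec.seed, **hp)
        if _degenerate_rate(successes, trials) is None:
            smooth_x, exog = learner._design(np.asarray(X, float))
            df = min(learner.spline_df, max(4, len(np.unique(smooth_x[:, 0]))))
            df2 = min(learner.spline_df, max(4, len(np.unique(smooth_x[:, 1]))))
            from statsmodels.gam.api import BSplines

            learner._bs = BSplines(smooth_x, df=[df, df2], degree=[3, 3])
            endog = np.column_stack([successes, trials - successes])
            alpha = learner._select_alpha(endog, exog, smooth_x)
            hp["alpha_grid"] = (alpha[0],)
    elif spec.learner == "l1_logistic" and "fixed_C" not in hp:
        learner = _L1Logistic(seed=spec.seed, **hp)
        model = learner.fit(np.asarray(X, float), successes, trials)
        if isinstance(model, _L1Logistic):
            hp["fixed_C"] = float(np.atleast_1d(model._clf.C_)[0])
    return ChildModelSpec(spec.learner, hp, spec.n_folds, spec.seed)


# --------------------------------------------------------------------------
# stacking


@dataclass
class StackedFeatures:
    """Out-of-sample child predictions per observation plus full-data child
    models; probabilities and their logits."""

    learners: list[str]
    oos_probs: np.ndarray  # (n_obs, n_learners)
    fold_labels: np.ndarray  # (n_obs,)
    full_models: list

    @property
    def oos_logits(self) -> np.ndarray:
        return logit(self.oos_probs)


def assign_folds(groups: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold label per observation; whole groups (clusters) share a fold."""
    uniq = np.unique(groups)
    if len(uniq) < n_folds:
        raise ValueError(f"need >= {n_folds} groups, got {len(uniq)}")
    rng = child_rng(seed, "stacking.folds")
    perm = rng.permutation(uniq)
    fold_of = {g: i % n_folds for i, g in enumerate(perm)}
    return np.array([fold_of[g] for g in groups])


def fit_children(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    groups: np.ndarray,
    specs: list[ChildModelSpec] | None = None,
    seed: int = 0,
) -> StackedFeatures:
    """K-fold out-of-sample stacking over the three child learners.

    ``groups`` identifies survey clusters; folds split clusters, not
    households, and every observation's stacked feature comes from children
    fitted without its own fold.
    """
    specs = specs if specs is not None else default_specs(seed=seed)
    n_folds = specs[0].n_folds
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    successes = np.asarray(successes, int)
    trials = np.asarray(trials, int)
    folds = assign_folds(np.asarray(groups), n_folds, seed)
    specs = [_tune_spec(s, X, successes, trials) for s in specs]
    oos = np.full((len(X), len(specs)), np.nan)
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        if not te.any():
            continue
        for j, spec in enumerate(specs):
            model = _make_learner(spec).fit(X[tr], successes[tr], trials[tr])
            oos[te, j] = model.predict(X[te])
    full = [_make_learner(s).fit(X, successes, trials) for s in specs]
    return StackedFeatures(
        learners=[s.learner for s in specs],
        oos_probs=clip_probs(oos),
        fold_labels=folds,
        full_models=full,
    )


def predict_child_rasters(
    stacked: StackedFeatures,
    covariates: np.ndarray,  # (n_covariates, n_cells)
    coords: np.ndarray,  # (n_cells, 2) rows/cols
    years: list[int],
    cells: np.ndarray | None = None,
) -> np.ndarray:
    """Per-child probability surfaces, shape (n_learners, n_cells, n_years).

    Deterministic given the fitted children; values clipped to the stacking
    probability range.
    """
    if not np.all(np.isfinite(covariates)):
        raise ValueError("missing covariate cell")
    idx = np.arange(covariates.shape[1]) if cells is None else np.asarray(cells)
    n_cells = len(idx)
    out = np.empty((len(stacked.full_models), n_cells, len(years)))
    for t, year in enumerate(years):
        Xp = np.column_stack(
            [covariates[:, idx].T, coords[idx], np.full(n_cells, float(year))]
        )
        for j, model in enumerate(stacked.full_models):
            out[j, :, t] = model.predict(Xp)
    return clip_probs(out)


def build_features(
    covariates: np.ndarray, coords: np.ndarray, cells: np.ndarray, years: np.ndarray
) -> np.ndarray:
    """Design matrix [covariates, row, col, year] for observations."""
    cells = np.asarray(cells)
    return np.column_stack(
        [covariates[:, cells].T, coords[cells], np.asarray(years, float)]
    )
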