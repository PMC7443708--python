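"""Spatially explicit binomial parent model with joint posterior draws.

The parent model for each conditional indicator and country is

    logit p(s, t) = x(s, t)' beta + u(s, t)

where ``x`` are the stacked child-model features (logit scale) and ``u`` is a
zero-mean Gaussian field with separable covariance: a spatial kernel (Matérn
ν=3/2 by default) in space times an AR1 correlation over years.  Fixed
effects carry a weakly informative Gaussian prior.

Inference is an exact Gaussian-field formulation on the grid: the latent
values at observed (cell, year) sites plus the fixed effects are found by
penalised Newton iteration (a Laplace approximation around the posterior
mode), and covariance hyperparameters (spatial SD, range, AR coefficient)
maximise the Laplace marginal likelihood plus weak priors.  Joint surface
draws combine draws from the Laplace Gaussian at the observed sites with
conditional simulation of the field at all prediction cells/years, using the
Kronecker structure of the separable covariance, so each draw preserves
spatial and temporal correlation.  An MCMC backend (random-walk Metropolis on
the same latent parameterisation) is selectable; the draw contract is
identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit

from washmap._rng import child_rng
from washmap.synthetic import KERNELS, ar1_chol

LOGIT_CLIP = 13.815510557964274  # logit(1 - 1e-6)


class FitError(RuntimeError):
    """Parent model failed to converge; carries diagnostics."""


@dataclass
class GeostatConfig:
    spatial_kernel: str = "matern32"
    n_draws: int = 250
    inference: str = "laplace"  # "laplace" | "mcmc"
    estimate_hyperparams: bool = True
    # initial values / prior modes for (spatial sd, range, AR coefficient)
    spatial_sd: float = 0.5
    spatial_range: float = 6.0
    temporal_ar: float = 0.9
    # prior scales on log sd, log range, atanh ar
    prior_scales: tuple[float, float, float] = (1.0, 0.75, 0.5)
    beta_prior_sd: float = 10.0
    max_opt_evals: int = 60
    mcmc_steps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_kernel not in KERNELS:
            raise ValueError(f"spatial_kernel must be one of {tuple(KERNELS)}")
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if self.inference not in ("laplace", "mcmc"):
            raise ValueError("inference must be 'laplace' or 'mcmc'")
        if not (-1.0 < self.temporal_ar < 1.0):
            raise ValueError("temporal_ar must lie in (-1, 1)")


@dataclass
class DrawCube:
    """Joint posterior draws of a probability surface.

    ``values`` has shape (n_cells, n_years, n_draws) on the probability
    scale; ``cells`` are flat grid indices, ``years`` calendar years.
    """

    values: np.ndarray
    cells: np.ndarray
    years: tuple[int, ...]
    indicator: str = ""
    conditional_level: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("draw cube must be (cells, years, draws)")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("draw cube values must lie in [0, 1]")

    @property
    def n_draws(self) -> int:
        return self.values.shape[2]

    def mean(self) -> np.ndarray:
        """Point estimate: the mean over draws, per cell and year."""
        return self.values.mean(axis=2)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values)
        meta = {
            "cells": [int(c) for c in self.cells],
            "years": list(self.years),
            "indicator": self.indicator,
            "conditional_level": self.conditional_level,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "DrawCube":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            values=np.load(path.with_suffix(".npy")),
            cells=np.array(meta["cells"]),
            years=tuple(meta["years"]),
            indicator=meta["indicator"],
            conditional_level=meta["conditional_level"],
            seed=meta["seed"],
        )


# --------------------------------------------------------------------------


def _binom_ll(eta, successes, trials):
    return float(np.sum(successes * eta - trials * np.logaddexp(0.0, eta)))


class ParentPosterior:
    """Fitted parent model: Laplace mode and curvature at observed sites,
    plus everything needed for conditional surface simulation."""

    def __init__(
        self,
        coords: np.ndarray,
        years: tuple[int, ...],
        X: np.ndarray,
        successes: np.ndarray,
        trials: np.ndarray,
        obs_cells: np.ndarray,
        obs_years: np.ndarray,
        config: GeostatConfig,
    ):
        self.coords = np.asarray(coords, float)
        self.years = tuple(int(y) for y in years)
        self.config = config
        self.X = np.asarray(X, float)
        if self.X.ndim != 2:
            raise ValueError("features must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")
        self.successes = np.asarray(successes, float)
        self.trials = np.asarray(trials, float)
        yr_index = {y: i for i, y in enumerate(self.years)}
        self.obs_cells = np.asarray(obs_cells, int)
        self.obs_years = np.array([yr_index[int(y)] for y in obs_years])
        # collapse observations to unique (cell, year index) sites
        keys = self.obs_cells * (len(self.years) + 1) + self.obs_years
        uniq, inv = np.unique(keys, return_inverse=True)
        self.site_of_obs = inv
        self.site_cell = uniq // (len(self.years) + 1)
        self.site_year = uniq % (len(self.years) + 1)
        self.m = len(uniq)
        self.p = self.X.shape[1]
        from scipy.spatial.distance import cdist

        self._dist = cdist(self.coords, self.coords)
        self.theta: np.ndarray | None = None
        self.converged = False

    # -- covariance pieces --------------------------------------------------

    def _mats(self, theta):
        sd = np.exp(theta[0])
        rho = np.exp(theta[1])
        ar = np.tanh(theta[2])
        Ks = KERNELS[self.config.spatial_kernel](self._dist, rho)
        idx = np.arange(len(self.years))
        Kt = ar ** np.abs(idx[:, None] - idx[None, :])
        K_sites = (sd**2) * Ks[np.ix_(self.site_cell, self.site_cell)] * Kt[
            np.ix_(self.site_year, self.site_year)
        ]
        K_sites[np.diag_indices_from(K_sites)] += 1e-8
        return sd, Ks, Kt, K_sites

    def _newton(self, K_sites, z0=None):
        """Penalised Newton for z = (beta, f_sites); returns mode, H, cho(H),
        log-likelihood at mode, gradient norm."""
        p, m = self.p, self.m
        tau2 = self.config.beta_prior_sd**2
        Kc = cho_factor(K_sites, lower=True)
        Kinv = cho_solve(Kc, np.eye(m))
        z = np.zeros(p + m) if z0 is None else z0.copy()
        S = self.site_of_obs
        ll = -np.inf
        for _ in range(100):
            beta, f = z[:p], z[p:]
            eta = self.X @ beta + f[S]
            mu = expit(eta)
            g_eta = self.successes - self.trials * mu
            w = np.maximum(self.trials * mu * (1.0 - mu), 1e-10)
            grad = np.concatenate(
                [
                    self.X.T @ g_eta - beta / tau2,
                    np.bincount(S, weights=g_eta, minlength=m) - Kinv @ f,
                ]
            )
            H = np.empty((p + m, p + m))
            H[:p, :p] = (self.X.T * w) @ self.X + np.eye(p) / tau2
            U = np.zeros((p, m))
            np.add.at(U.T, S, (self.X.T * w).T)
            H[:p, p:] = U
            H[p:, :p] = U.T
            H[p:, p:] = Kinv
            H[p:, p:][np.diag_indices(m)] += np.bincount(S, weights=w, minlength=m)
            Hc = cho_factor(H, lower=True)
            step = cho_solve(Hc, grad)
            # step halving on the penalised objective
            obj0 = (
                _binom_ll(eta, self.successes, self.trials)
                - 0.5 * beta @ beta / tau2
                - 0.5 * f @ (Kinv @ f)
            )
            scale = 1.0
            for _ in range(30):
                z_new = z + scale * step
                b_n, f_n = z_new[:p], z_new[p:]
                eta_n = self.X @ b_n + f_n[S]
                obj = (
                    _binom_ll(eta_n, self.successes, self.trials)
                    - 0.5 * b_n @ b_n / tau2
                    - 0.5 * f_n @ (Kinv @ f_n)
                )
                if obj >= obj0 - 1e-12:
                    break
                scale *= 0.5
            z = z + scale * step
            gnorm = float(np.max(np.abs(grad)))
            if gnorm < 1e-6:
                break
        ll = _binom_ll(self.X @ z[:p] + z[p:][S], self.successes, self.trials)
        return z, H, Hc, Kc, Kinv, ll, gnorm

    def _log_marginal(self, theta):
        _, _, _, K_sites = self._mats(theta)
        try:
            z, H, Hc, Kc, Kinv, ll, gnorm = self._newton(K_sites)
        except np.linalg.LinAlgError:
            return -np.inf
        tau2 = self.config.beta_prior_sd**2
        beta, f = z[: self.p], z[self.p :]
        logdet_K = 2.0 * np.sum(np.log(np.diag(Kc[0])))
        logdet_H = 2.0 * np.sum(np.log(np.diag(Hc[0])))
        lml = (
            ll
            - 0.5 * beta @ beta / tau2
            - 0.5 * f @ (Kinv @ f)
            - 0.5 * logdet_K
            - 0.5 * logdet_H
        )
        # weak priors on the hyperparameters (location = config initials)
        c = self.config
        mu = np.array([np.log(c.spatial_sd), np.log(c.spatial_range), np.arctanh(c.temporal_ar)])
        sc = np.asarray(c.prior_scales)
        lml -= 0.5 * float(np.sum(((theta - mu) / sc) ** 2))
        return lml

    def fit(self) -> "ParentPosterior":
        c = self.config
        theta0 = np.array(
            [np.log(c.spatial_sd), np.log(c.spatial_range), np.arctanh(c.temporal_ar)]
        )
        if c.estimate_hyperparams:
            res = minimize(
                lambda t: -self._log_marginal(t),
                theta0,
                method="Nelder-Mead",
                options={
                    "maxfev": c.max_opt_evals,
                    "xatol": 0.05,
                    "fatol": 0.05,
                },
            )
            self.theta = res.x
        else:
            self.theta = theta0
        sd, Ks, Kt, K_sites = self._mats(self.theta)
        z, H, Hc, Kc, Kinv, ll, gnorm = self._newton(K_sites)
        if gnorm > 1e-4:
            raise FitError(
                f"Newton did not converge: max|grad|={gnorm:.3e} "
                f"(m={self.m}, p={self.p}, theta={self.theta})"
            )
        self.mode = z
        self._H = H
        self._LH = np.linalg.cholesky(H)
        self._Kc = Kc
        self.sd = sd
        self._Ks = Ks
        self._Kt = Kt
        self.loglik_at_mode = ll
        self.converged = True
        if c.inference == "mcmc":
            self._run_mcmc()
        return self

    # -- MCMC backend -------------------------------------------------------

    def _run_mcmc(self):
        """Preconditioned random-walk Metropolis on z, started at the Laplace
        mode and scaled by the Laplace curvature.  Same draw contract."""
        c = self.config
        rng = child_rng(c.seed, "parent.mcmc")
        p, m = self.p, self.m
        tau2 = c.beta_prior_sd**2
        Kinv = cho_solve(self._Kc, np.eye(m))
        S = self.site_of_obs

        def logpost(z):
            beta, f = z[:p], z[p:]
            eta = self.X @ beta + f[S]
            return (
                _binom_ll(eta, self.successes, self.trials)
                - 0.5 * beta @ beta / tau2
                - 0.5 * f @ (Kinv @ f)
            )

        z = self.mode.copy()
        lp = logpost(z)
        step = 2.4 / np.sqrt(p + m)
        # proposal covariance = Laplace covariance
        samples = []
        keep_every = max(1, c.mcmc_steps // max(c.n_draws, 1))
        n_acc = 0
        for it in range(c.mcmc_steps):
            xi = rng.standard_normal(p + m)
            prop = z + step * np.linalg.solve(self._LH.T, xi)
            lp_prop = logpost(prop)
            if np.log(rng.random()) < lp_prop - lp:
                z, lp = prop, lp_prop
                n_acc += 1
            if it % keep_every == 0:
                samples.append(z.copy())
        self._mcmc_samples = np.array(samples)
        self.mcmc_accept = n_acc / self.config.mcmc_steps

    # -- draws --------------------------------------------------------------

    def _draw_latent(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """(n_draws, p+m) draws of (beta, f_sites)."""
        if self.config.inference == "mcmc":
            samp = self._mcmc_samples
            idx = rng.integers(0, len(samp), size=n_draws)
            return samp[idx]
        xi = rng.standard_normal((n_draws, self.p + self.m))
        return self.mode + np.linalg.solve(self._LH.T, xi.T).T

    def sample_surface(
        self,
        n_draws: int | None = None,
        seed: int | None = None,
        X_pred: np.ndarray | None = None,
        cells: np.ndarray | None = None,
    ) -> DrawCube:
        """Joint probability-surface draws at all cells/years.

        ``X_pred`` has shape (n_cells, n_years, p) — the stacked-feature
        rasters; omit it for an intercept-only surface.  ``cells`` labels the
        output cube with flat grid indices (defaults to 0..n_cells-1).
        """
        if not self.converged:
            raise FitError("posterior not fitted")
        c = self.config
        n_draws = c.n_draws if n_draws is None else int(n_draws)
        if n_draws > c.n_draws:
            raise ValueError(f"n_draws {n_draws} exceeds configured maximum {c.n_draws}")
        seed = c.seed if seed is None else seed
        rng = child_rng(seed, "parent.draws")
        n_cells = len(self.coords)
        n_years = len(self.years)
        if X_pred is None:
            X_pred = np.ones((n_cells, n_years, 1))
        X_pred = np.asarray(X_pred, float)
        if X_pred.shape != (n_cells, n_years, self.p):
            raise ValueError("X_pred must be (n_cells, n_years, n_features)")

        Ks = self._Ks.copy()
        Ks[np.diag_indices_from(Ks)] += 1e-8
        Ls = np.linalg.cholesky(Ks)
        Lt = np.linalg.cholesky(self._Kt + 1e-10 * np.eye(n_years))
        # cross-covariance between every prediction site and observed sites
        Kps = (self.sd**2) * (
            Ks[:, self.site_cell][:, None, :] * self._Kt[:, self.site_year][None, :, :]
        )  # (n_cells, n_years, m)

        zdraws = self._draw_latent(n_draws, rng)
        out = np.empty((n_cells, n_years, n_draws))
        for d in range(n_draws):
            beta = zdraws[d, : self.p]
            f = zdraws[d, self.p :]
            G = rng.standard_normal((n_cells, n_years))
            U0 = self.sd * (Ls @ G @ Lt.T)
            resid = f - U0[self.site_cell, self.site_year]
            alpha = cho_solve(self._Kc, resid)
            u = U0 + Kps @ alpha
            eta = X_pred @ beta + u
            out[:, :, d] = expit(np.clip(eta, -LOGIT_CLIP, LOGIT_CLIP))
        return DrawCube(
            values=out,
            cells=np.arange(n_cells) if cells is None else np.asarray(cells),
            years=self.years,
            seed=seed,
        )


def fit_parent(
    coords: np.ndarray,
    years: tuple[int, ...],
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    obs_cells: np.ndarray,
    obs_years: np.ndarray,
    config: GeostatConfig | None = None,
) -> ParentPosterior:
    """Fit the spatial binomial parent model; returns a posterior able to
    produce joint draw cubes.  ``obs_cells`` index rows of ``coords``;
    ``obs_years`` are calendar years."""
    config = config if config is not None else GeostatConfig()
    if len(successes) == 0:
        raise ValueError("no observations")
    post = ParentPosterior(
        coords, years, X, successes, trials, obs_cells, obs_years, config
    )
    return post.fit()
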