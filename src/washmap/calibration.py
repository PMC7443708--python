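"""National calibration (raking) of gridded draws.

A penalised-spline binomial trend on calendar year is fitted to nationally
representative data per country and conditional level; the gridded draw
cubes are then raked so that national population-weighted aggregates match
the national series: for each draw and year independently, a single additive
logit shift δ is found by monotone root-finding and applied uniformly over
cells.  A uniform logit shift never reorders cells, and larger targets give
strictly larger δ.

Raking operates in continuation-ratio space so the mutually exclusive
category structure survives calibration: national category targets are
converted to conditional targets, and each conditional level is raked
against its conditional target using the population at risk at that level
(population times the raked probability of reaching the level) as weights —
with those weights the recombined categories aggregate exactly to all four
national category targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from washmap.ordinal import conditional_from_category, to_conditional_observations
from washmap.records import SurveyRecord
from washmap.spatial import DrawCube

TARGET_CLIP = (1e-4, 1.0 - 1e-4)
DELTA_BRACKET = 20.0


@dataclass
class NationalSeries:
    """Calibrated national target probabilities per study year for one
    country and conditional level."""

    country: str
    conditional_level: int
    years: tuple[int, ...]
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, float)
        if np.any(self.targets <= 0) or np.any(self.targets >= 1):
            raise ValueError("national targets must lie in (0, 1)")


def fit_national_model(
    records: list[SurveyRecord],
    country: str,
    conditional_level: int,
    years: tuple[int, ...],
) -> NationalSeries:
    """Binomial trend on year from nationally representative records.

    Penalised-spline (GAM) trend with >= 5 year points; linear logit trend
    otherwise.  Needs at least 3 year points, else the country is excluded
    from calibration (raised as ValueError).
    """
    import statsmodels.api as sm

    rows = []
    for r in records:
        if r.country != country:
            continue
        for level, s, n in to_conditional_observations(r):
            if level == conditional_level:
                rows.append((r.year, s, n))
    if not rows:
        raise ValueError(f"no nationally representative data for {country}")
    rows.sort()  # order-invariance under record permutation
    yr = np.array([r[0] for r in rows], float)
    s = np.array([r[1] for r in rows], float)
    n = np.array([r[2] for r in rows], float)
    if len(np.unique(yr)) < 3:
        raise ValueError(
            f"{country}: need >= 3 year points for the national model, "
            f"got {len(np.unique(yr))}"
        )
    endog = np.column_stack([s, n - s])
    grid = np.asarray(years, float)
    if len(np.unique(yr)) >= 5:
        from statsmodels.gam.api import BSplines, GLMGam

        bs = BSplines(yr[:, None], df=[5], degree=[3], include_intercept=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = GLMGam(
                endog,
                exog=np.ones((len(yr), 1)),
                smoother=bs,
                alpha=[1.0],
                family=sm.families.Binomial(),
            ).fit(maxiter=100)
        basis = bs.transform(np.clip(grid, yr.min(), yr.max())[:, None])
        eta = res.params[0] + basis @ res.params[1:]
    else:
        exog = np.column_stack([np.ones_like(yr), yr - yr.mean()])
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        eta = res.params[0] + res.params[1] * (grid - yr.mean())
    fitted = np.clip(expit(eta), *TARGET_CLIP)
    return NationalSeries(country, conditional_level, tuple(years), fitted)


# --------------------------------------------------------------------------
# raking


def _rake_delta(p: np.ndarray, w: np.ndarray, target: float, tol: float) -> float:
    """Uniform logit shift matching the weighted aggregate to the target."""
    if not (0.0 < target < 1.0):
        raise ValueError(f"rake target must lie in (0, 1), got {target}")
    eta = logit(np.clip(p, 1e-12, 1 - 1e-12))
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("population must be positive somewhere")

    def agg(delta: float) -> float:
        return float((w * expit(eta + delta)).sum() / wsum) - target

    lo, hi = -DELTA_BRACKET, DELTA_BRACKET
    flo, fhi = agg(lo), agg(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(f"rake target {target} not bracketable within ±{DELTA_BRACKET}")
    return brentq(agg, lo, hi, xtol=tol)


def logit_rake(
    cube: DrawCube,
    population: np.ndarray,
    targets: np.ndarray,
    tolerance: float = 1e-8,
    weights: np.ndarray | None = None,
) -> tuple[DrawCube, np.ndarray]:
    """Rake a draw cube to per-year national targets.

    ``targets`` is scalar or (n_years,).  ``weights`` defaults to the static
    population but may be draw-dependent with shape (n_cells, n_years,
    n_draws) for continuation-ratio raking.  Returns the raked cube and the
    per-(year, draw) logit shifts δ.
    """
    n_cells, n_years, n_draws = cube.values.shape
    targets = np.broadcast_to(np.asarray(targets, float), (n_years,))
    pop = np.asarray(population, float)
    raked = np.empty_like(cube.values)
    delta = np.empty((n_years, n_draws))
    for t in range(n_years):
        for d in range(n_draws):
            w = pop if weights is None else weights[:, t, d]
            dd = _rake_delta(cube.values[:, t, d], w, float(targets[t]), tolerance)
            delta[t, d] = dd
            eta = logit(np.clip(cube.values[:, t, d], 1e-12, 1 - 1e-12))
            raked[:, t, d] = expit(eta + dd)
    out = DrawCube(
        values=raked,
        cells=cube.cells,
        years=cube.years,
        indicator=cube.indicator,
        conditional_level=cube.conditional_level,
        seed=cube.seed,
    )
    return out, delta


def rake_continuation_ratio(
    cubes: list[DrawCube],
    national_category: np.ndarray,
    population: np.ndarray,
    tolerance: float = 1e-8,
) -> tuple[list[DrawCube], list[np.ndarray]]:
    """Rake the three conditional cubes to national category targets.

    ``national_category`` has shape (4, n_years) and must be a valid
    probability vector per year.  Level 1 is raked with population weights;
    levels 2 and 3 with the population still at risk under the already-raked
    upstream levels, which makes all four recombined category aggregates hit
    the national targets exactly (up to the root-finder tolerance).
    """
    if len(cubes) != 3:
        raise ValueError("need the three conditional draw cubes")
    cat = np.asarray(national_category, float)
    if cat.shape[0] != 4:
        raise ValueError("national_category must be (4, n_years)")
    if np.any(np.abs(cat.sum(axis=0) - 1.0) > 1e-6):
        raise ValueError("national category targets must sum to 1")
    cond_targets = conditional_from_category(cat)  # (3, n_years)
    pop = np.asarray(population, float)
    raked: list[DrawCube] = []
    deltas: list[np.ndarray] = []
    # survival weights: population at risk entering each level, per draw
    at_risk = np.broadcast_to(
        pop[:, None, None], cubes[0].values.shape
    ).copy()
    for level in range(3):
        cube_r, delta = logit_rake(
            cubes[level],
            pop,
            np.clip(cond_targets[level], *TARGET_CLIP),
            tolerance,
            weights=at_risk,
        )
        raked.append(cube_r)
        deltas.append(delta)
        at_risk = at_risk * (1.0 - cube_r.values)
    return raked, deltas


def national_series_frame(series: list[NationalSeries], indicator: str = "") -> pd.DataFrame:
    rows = []
    for s in series:
        for y, t in zip(s.years, s.targets):
            rows.append(
                {
                    "country": s.country,
                    "indicator": indicator,
                    "conditional_level": s.conditional_level,
                    "year": y,
                    "target": t,
                }
            )
    return pd.DataFrame(rows)
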