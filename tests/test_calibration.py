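"""National trend model and continuation-ratio raking."""

import numpy as np
import pytest

from washmap.calibration import (
    NationalSeries,
    fit_national_model,
    logit_rake,
    rake_continuation_ratio,
)
from washmap.ordinal import recombine
from washmap.records import SurveyRecord
from washmap.spatial import DrawCube

YEARS = tuple(range(2000, 2018))


def _national_records(probs_by_year, n=5000, country="C0", seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for year, p1 in probs_by_year.items():
        n1 = rng.binomial(n, p1)
        rest = n - n1
        recs.append(
            SurveyRecord(
                record_id=f"nat-{year}", source_type="areal", country=country,
                polygon=country, year=year, N=n,
                counts=np.array([n1, rest, 0, 0]),
            )
        )
    return recs


def test_constant_truth_recovered():
    """Flat truth of 0.5 across all years, large N -> fitted national series
    within [0.48, 0.52] everywhere."""
    recs = _national_records({y: 0.5 for y in YEARS}, n=20000, seed=1)
    series = fit_national_model(recs, "C0", 1, YEARS)
    assert np.all(series.targets > 0.48) and np.all(series.targets < 0.52)


def test_fitted_values_in_open_interval():
    recs = _national_records({y: 0.999 for y in YEARS}, n=500, seed=2)
    series = fit_national_model(recs, "C0", 1, YEARS)
    assert np.all(series.targets > 0) and np.all(series.targets < 1)


def test_order_invariance():
    recs = _national_records({y: 0.3 + 0.01 * (y - 2000) for y in YEARS}, seed=3)
    a = fit_national_model(recs, "C0", 1, YEARS)
    b = fit_national_model(list(reversed(recs)), "C0", 1, YEARS)
    assert np.array_equal(a.targets, b.targets)


def test_linear_fallback_under_five_points():
    recs = _national_records({2000: 0.3, 2008: 0.4, 2016: 0.5}, n=50000, seed=4)
    series = fit_national_model(recs, "C0", 1, YEARS)
    # logit-linear interpolation should be monotone here
    assert np.all(np.diff(series.targets) > 0)


def test_insufficient_data_excludes_country():
    recs = _national_records({2000: 0.3, 2010: 0.4}, seed=5)
    with pytest.raises(ValueError, match="3 year"):
        fit_national_model(recs, "C0", 1, YEARS)
    with pytest.raises(ValueError, match="no nationally representative"):
        fit_national_model(recs, "C9", 1, YEARS)


def test_targets_validated():
    with pytest.raises(ValueError):
        NationalSeries("C0", 1, (2000,), np.array([1.5]))


# -- raking ----------------------------------------------------------------


def _cube(values, years=(2000,)):
    values = np.asarray(values, float)
    return DrawCube(values, np.arange(values.shape[0]), years)


def test_single_cell_closed_form():
    """One cell at p=0.25 raked to 0.5 needs delta = logit(0.5) - logit(0.25)
    = log 3."""
    cube = _cube(np.full((1, 1, 3), 0.25))
    raked, delta = logit_rake(cube, np.array([2.0]), 0.5)
    assert np.allclose(delta, np.log(3.0), atol=1e-7)
    assert np.allclose(raked.values, 0.5, atol=1e-8)


def test_fixed_point_leaves_cube_unchanged():
    rng = np.random.default_rng(6)
    vals = rng.uniform(0.2, 0.8, (5, 2, 4))
    pop = rng.uniform(1, 10, 5)
    agg = np.tensordot(pop, vals, axes=(0, 0)) / pop.sum()  # (years, draws)
    cube = _cube(vals, years=(2000, 2001))
    for t in range(2):
        for d in range(4):
            raked, delta = logit_rake(
                _cube(vals[:, t : t + 1, d : d + 1]), pop, agg[t, d]
            )
            assert abs(delta[0, 0]) < 1e-7
            assert np.allclose(raked.values, vals[:, t : t + 1, d : d + 1], atol=1e-7)


def test_raking_defining_property_and_order_preservation():
    rng = np.random.default_rng(7)
    vals = rng.uniform(0.05, 0.95, (30, 3, 8))
    pop = rng.uniform(1, 100, 30)
    cube = _cube(vals, years=(2000, 2001, 2002))
    targets = np.array([0.3, 0.5, 0.7])
    raked, delta = logit_rake(cube, pop, targets)
    agg = np.tensordot(pop, raked.values, axes=(0, 0)) / pop.sum()
    assert np.max(np.abs(agg - targets[:, None])) < 1e-8
    # a uniform logit shift never reorders cells
    for t in range(3):
        for d in range(8):
            assert np.array_equal(
                np.argsort(vals[:, t, d]), np.argsort(raked.values[:, t, d])
            )
    # monotonicity: larger target => larger delta (same year, same cube)
    assert np.all(delta[2] > delta[1]) and np.all(delta[1] > delta[0])


def test_unbracketable_target_rejected():
    cube = _cube(np.full((2, 1, 1), 0.5))
    with pytest.raises(ValueError):
        logit_rake(cube, np.ones(2), 1.0)


def test_continuation_ratio_raking_hits_all_four_targets():
    rng = np.random.default_rng(8)
    n_cells, n_years, n_draws = 25, 4, 10
    years = tuple(range(2000, 2000 + n_years))
    pop = rng.uniform(10, 1000, n_cells)
    cubes = [
        _cube(rng.uniform(0.1, 0.9, (n_cells, n_years, n_draws)), years)
        for _ in range(3)
    ]
    target = np.array([0.4, 0.3, 0.15, 0.15])[:, None] * np.ones((1, n_years))
    raked, deltas = rake_continuation_ratio(cubes, target, pop)
    cat = recombine(np.stack([c.values for c in raked]))
    agg = np.einsum("c,kctd->ktd", pop, cat) / pop.sum()
    assert np.max(np.abs(agg - target[:, :, None])) < 1e-6
    # sum-to-one preserved cell-wise
    assert np.max(np.abs(cat.sum(axis=0) - 1.0)) <= 1e-12


def test_continuation_ratio_raking_uniform_cube_gives_zero_deltas():
    n_cells, n_years, n_draws = 10, 2, 3
    years = (2000, 2001)
    pop = np.ones(n_cells)
    cond = (0.4, 0.5, 0.5)  # recombines to (0.4, 0.3, 0.15, 0.15)
    cubes = [_cube(np.full((n_cells, n_years, n_draws), q), years) for q in cond]
    target = np.array([0.4, 0.3, 0.15, 0.15])[:, None] * np.ones((1, n_years))
    _, deltas = rake_continuation_ratio(cubes, target, pop)
    for d in deltas:
        assert np.max(np.abs(d)) < 1e-6
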