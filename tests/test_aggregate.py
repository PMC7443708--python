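"""Admin aggregation, change metrics, dominant types, transitions."""

import numpy as np
import pytest

from washmap.aggregate import (
    aggregate_unit,
    classify_dominant,
    count_without_access,
    high_access_share,
    mean_annual_change,
    transition_type,
)
from washmap.spatial import DrawCube


def _cube(values, years=(2000,)):
    values = np.asarray(values, float)
    return DrawCube(values, np.arange(values.shape[0]), years)


def test_weighted_mean_example():
    cube = _cube(np.array([[[0.1]], [[0.5]]]))
    out = aggregate_unit(cube, np.array([0, 1]), np.array([100.0, 300.0]))
    assert out[0, 0] == pytest.approx(0.4)


def test_constant_surface_invariance():
    cube = _cube(np.full((7, 2, 3), 0.37), years=(2000, 2001))
    out = aggregate_unit(cube, np.arange(7), np.random.default_rng(0).uniform(1, 9, 7))
    assert np.allclose(out, 0.37)


def test_nested_aggregation_consistency():
    """Admin2 -> country aggregation equals direct country aggregation."""
    rng = np.random.default_rng(1)
    vals = rng.uniform(0, 1, (12, 2, 5))
    pop = rng.uniform(1, 50, 12)
    cube = _cube(vals, years=(2000, 2001))
    units = [np.arange(0, 4), np.arange(4, 9), np.arange(9, 12)]
    per_unit = [aggregate_unit(cube, u, pop[u]) for u in units]
    unit_pops = np.array([pop[u].sum() for u in units])
    nested = np.tensordot(unit_pops, np.stack(per_unit), axes=(0, 0)) / unit_pops.sum()
    direct = aggregate_unit(cube, np.arange(12), pop)
    assert np.max(np.abs(nested - direct)) < 1e-12


def test_zero_population_unit_rejected():
    cube = _cube(np.full((2, 1, 1), 0.5))
    with pytest.raises(ValueError, match="zero population"):
        aggregate_unit(cube, np.array([0, 1]), np.zeros(2))


@pytest.mark.parametrize(
    "first, last, expected",
    [
        (23.5, 47.6, 1.3),   # Niger piped water
        (0.0, 49.3, 2.7),    # Rapti District sewer/septic increase
        (0.0, 35.9, 2.0),    # San Pedro Sula sewer/septic increase
    ],
)
def test_mean_annual_change_reported_values(first, last, expected):
    """The 2000-2017 span is 18 years; printed values are 1 d.p."""
    assert round(float(mean_annual_change(first, last)), 1) == expected


def test_count_without_access():
    assert count_without_access(np.array([0.75]), 1000.0)[0] == 250.0
    assert count_without_access(np.array([1.0]), 1000.0)[0] == 0.0
    # monotone decreasing: upper access bound gives the lower count bound
    draws = np.array([0.2, 0.5, 0.9])
    counts = count_without_access(draws, 100.0)
    assert counts.argmin() == draws.argmax()


@pytest.mark.parametrize(
    "shares, label",
    [
        ((0.65, 0.20, 0.15), "improved"),
        ((0.55, 0.25, 0.20), "mixed"),
        ((0.60, 0.30, 0.10), "mixed"),  # strict inequality at the boundary
        ((0.10, 0.20, 0.70), "none"),
    ],
)
def test_classify_dominant(shares, label):
    out = classify_dominant(*[np.array([v]) for v in shares])
    assert out[0] == label


def test_classify_dominant_validates_shares():
    with pytest.raises(ValueError, match="sum to 1"):
        classify_dominant(np.array([0.5]), np.array([0.1]), np.array([0.1]))


@pytest.mark.parametrize(
    "pair, expected",
    [
        (("none", "improved"), "substantial_upgrade"),
        (("none", "unimproved"), "incremental_upgrade"),
        (("unimproved", "improved"), "incremental_upgrade"),
        (("improved", "improved"), "other"),
        (("improved", "none"), "other"),
        (("mixed", "improved"), "other"),
    ],
)
def test_transition_typology(pair, expected):
    assert transition_type(*pair) == expected


def test_transition_rejects_unknown_labels():
    with pytest.raises(ValueError):
        transition_type("none", "great")


def test_high_access_share():
    allhigh = high_access_share(np.full((5, 10), 0.9))
    assert allhigh["mean"] == 1.0
    none = high_access_share(np.full((5, 10), 0.5))
    assert none["mean"] == 0.0
    mixed = high_access_share(np.vstack([np.full((2, 10), 0.95), np.full((3, 10), 0.1)]))
    assert 0.0 <= mixed["lower"] <= mixed["mean"] <= mixed["upper"] <= 1.0
    assert mixed["mean"] == pytest.approx(0.4)
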