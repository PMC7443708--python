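"""Synthetic world generator and survey simulators."""

import numpy as np
import pytest

from washmap.synthetic import (
    WorldConfig,
    generate_world,
    simulate_areal_survey,
    simulate_national_series,
    simulate_point_survey,
)


def test_seeded_determinism(world):
    again = generate_world(world.config)
    assert np.array_equal(again.true_category, world.true_category)
    assert np.array_equal(again.population.values, world.population.values)
    assert np.array_equal(again.covariates.values, world.covariates.values)


def test_truth_is_valid_probability_surface(world):
    cat = world.true_category
    assert np.max(np.abs(cat.sum(axis=0) - 1.0)) <= 1e-12
    assert np.all(cat >= 0) and np.all(cat <= 1)
    # conditional logits finite => conditionals strictly inside (0, 1)
    assert np.all(world.true_conditional > 0) and np.all(world.true_conditional < 1)


def test_population_normalised(world):
    assert abs(world.population.values.sum() - world.config.total_population) < 1.0


def test_admin_partition(world):
    adm = world.admin
    # every cell in exactly one admin2; populations nest exactly
    total = sum(adm.population_of(u) for u in adm.units("admin2"))
    assert total == pytest.approx(world.config.total_population, rel=1e-9)
    for unit in adm.units("admin2"):
        assert adm.parent(adm.parent(unit)) in adm.units("country")


def test_rejects_empty_admin2():
    with pytest.raises(ValueError):
        generate_world(WorldConfig(n_rows=4, n_cols=4, n_countries=4,
                                   admin1_per_country=2, admin2_per_admin1=5))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        WorldConfig(years=(2005, 2003))
    with pytest.raises(ValueError):
        WorldConfig(temporal_ar=1.5)
    with pytest.raises(ValueError):
        WorldConfig(total_population=-5)


def test_point_survey_contract(world):
    recs = simulate_point_survey(world, "C0", 2005, 12, 25, seed=3)
    assert len(recs) == 12
    for r in recs:
        assert r.counts.sum() == r.N == 25
        assert r.cell is not None and r.polygon is None
    assert simulate_point_survey(world, "C0", 2005, 0, 25, seed=3) == []
    again = simulate_point_survey(world, "C0", 2005, 12, 25, seed=3)
    assert all(np.array_equal(a.counts, b.counts) and a.cell == b.cell
               for a, b in zip(recs, again))


def test_point_survey_sampling_error_bound(constant_truth_world):
    """500 clusters of N=25 at constant truth: pooled fractions within 3
    standard errors of (0.4, 0.3, 0.2, 0.1)."""
    recs = simulate_point_survey(constant_truth_world, "C0", 2005, 500, 25, seed=5)
    pooled = sum(r.counts for r in recs) / (500 * 25)
    truth = np.array([0.4, 0.3, 0.2, 0.1])
    se = np.sqrt(truth * (1 - truth) / (500 * 25))
    assert np.all(np.abs(pooled - truth) <= 3 * se)


def test_areal_survey_contract(world):
    recs = simulate_areal_survey(world, "C1", 2010, "admin1", 300, seed=4)
    assert {r.polygon for r in recs} == {"C1A0", "C1A1"}
    for r in recs:
        assert r.cell is None and r.counts.sum() == r.N == 300
    with pytest.raises(KeyError):
        world.admin.cells_of("C9A0")


def test_areal_matches_point_expectation_under_constant_truth(constant_truth_world):
    """A unit whose cells share identical truth gives areal counts with the
    same expectation as pooled point sampling at that truth."""
    w = constant_truth_world
    n = 20000
    areal = simulate_areal_survey(w, "C0", 2005, "admin1", n, seed=6)
    truth = np.array([0.4, 0.3, 0.2, 0.1])
    for r in areal:
        se = np.sqrt(truth * (1 - truth) / n)
        assert np.all(np.abs(r.counts / n - truth) <= 4 * se)


def test_national_series_contract(world):
    recs = simulate_national_series(world, "C2", seed=8)
    assert [r.year for r in recs] == list(world.years)
    for r in recs:
        assert r.polygon == "C2" and r.N == 4000 and r.counts.sum() == 4000


def test_monotone_information():
    """Doubling the cluster count shrinks the Monte-Carlo SE of the pooled
    category-1 fraction by ≈ √2 (50 replicate seeds, 20% tolerance)."""
    w = generate_world(WorldConfig(seed=21))

    def pooled_sd(n_clusters):
        vals = []
        for s in range(50):
            recs = simulate_point_survey(w, "C0", 2008, n_clusters, 25, seed=1000 + s)
            vals.append(sum(r.counts[0] for r in recs) / (n_clusters * 25))
        return np.std(vals)

    ratio = pooled_sd(10) / pooled_sd(20)
    assert ratio == pytest.approx(np.sqrt(2), rel=0.20)
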