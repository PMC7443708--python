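"""Comparative risk assessment: exposures, PAFs, attributable/averted deaths."""

import numpy as np
import pandas as pd
import pytest

from washmap.burden import (
    RiskRatioTable,
    SANITATION_EXPOSURE_IDS,
    attributable_deaths,
    averted_deaths,
    build_water_exposure,
    paf,
    synthetic_risk_ratio_frame,
)


@pytest.fixture
def rr2():
    return RiskRatioTable("sanitation", ("ref", "risky"), np.array([1.0, 3.0]), "ref")


def test_rr_table_validation():
    with pytest.raises(ValueError, match="reference"):
        RiskRatioTable("water", ("a", "b"), np.array([1.0, 2.0]), "c")
    with pytest.raises(ValueError, match=">= 1"):
        RiskRatioTable("water", ("a", "b"), np.array([1.0, 0.8]), "a")
    df = synthetic_risk_ratio_frame()
    for domain in ("water", "sanitation"):
        t = RiskRatioTable.from_frame(df, domain)
        assert t.rr[t.exposure_ids.index(t.reference)] == 1.0


def test_water_exposure_product_structure():
    p = np.array([0.5, 0.5, 0.0, 0.0])
    e = build_water_exposure(p, 0.5)
    assert np.allclose(e[:4], 0.25) and np.allclose(e[4:], 0.0)
    assert e.sum() == pytest.approx(1.0)
    # t=0: all mass on the untreated slots, facility distribution preserved
    e0 = build_water_exposure(np.array([0.4, 0.3, 0.2, 0.1]), 0.0)
    assert np.allclose(e0[0::2], 0.0)
    assert np.allclose(e0[1::2], [0.4, 0.3, 0.2, 0.1])
    with pytest.raises(ValueError):
        build_water_exposure(p, 1.5)


def test_exposure_sums_to_one_for_random_inputs():
    rng = np.random.default_rng(0)
    p = rng.dirichlet(np.ones(4), size=200).T
    t = rng.uniform(0, 1, 200)
    e = build_water_exposure(p, t)
    assert np.max(np.abs(e.sum(axis=0) - 1.0)) < 1e-12


def test_paf_closed_form(rr2):
    """Half the population at RR 3: RW = 2, PAF = 0.5."""
    assert paf(np.array([0.5, 0.5]), rr2) == pytest.approx(0.5)
    assert paf(np.array([1.0, 0.0]), rr2) == pytest.approx(0.0)


def test_paf_monotone_under_mass_transfer(rr2):
    """Moving mass from the reference to any RR>1 category raises the PAF."""
    rng = np.random.default_rng(1)
    for _ in range(200):
        p = rng.dirichlet(np.ones(2))
        if p[0] < 0.05:
            continue
        shift = np.array([-0.04, 0.04])
        assert paf(p + shift, rr2) > paf(p, rr2)


def test_paf_invariant_to_nonreference_relabelling():
    rr_a = RiskRatioTable("water", ("ref", "x", "y"), np.array([1.0, 2.0, 3.0]), "ref")
    rr_b = RiskRatioTable("water", ("ref", "y", "x"), np.array([1.0, 3.0, 2.0]), "ref")
    p = np.array([0.5, 0.3, 0.2])
    assert paf(p, rr_a) == pytest.approx(paf(p[[0, 2, 1]], rr_b))


def test_paf_input_validation(rr2):
    with pytest.raises(ValueError, match="categories"):
        paf(np.array([0.2, 0.3, 0.5]), rr2)
    with pytest.raises(ValueError, match="sum to 1"):
        paf(np.array([0.2, 0.2]), rr2)


def test_attributable_deaths():
    assert attributable_deaths(100.0, np.array([0.5]))[0] == 50.0
    assert attributable_deaths(100.0, np.array([0.0]))[0] == 0.0
    # additive over units
    pafs = np.array([0.2, 0.3])
    assert attributable_deaths(np.array([100.0, 200.0]), pafs).sum() == 80.0


def test_averted_deaths_closed_form(rr2):
    """RW 3 -> 2 with 100 observed deaths: counterfactual 150, 50 averted."""
    e2000 = np.array([0.0, 1.0])  # RW = 3
    e2017 = np.array([0.5, 0.5])  # RW = 2
    assert averted_deaths(100.0, e2000, e2017, rr2) == pytest.approx(50.0)
    # unchanged exposure -> zero averted
    assert averted_deaths(100.0, e2017, e2017, rr2) == pytest.approx(0.0)
    # worsening access -> negative (deaths caused)
    assert averted_deaths(100.0, e2017, e2000, rr2) < 0


def test_averted_sign_flips_when_years_swap(rr2):
    rng = np.random.default_rng(2)
    for _ in range(50):
        a = rng.dirichlet(np.ones(2))
        b = rng.dirichlet(np.ones(2))
        fwd = averted_deaths(100.0, a, b, rr2)
        rev = averted_deaths(100.0, b, a, rr2)
        assert fwd * rev <= 1e-12  # opposite signs (or both zero)


def test_sanitation_ids_align_with_category_count():
    assert len(SANITATION_EXPOSURE_IDS) == 4
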