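"""Admin-unit aggregation and derived policy metrics.

All uncertainty is computed draw-wise: any function of the surface (unit
access, counts without access, dominant-type labels, transition classes,
high-access shares) is evaluated per posterior draw first and summarised
afterwards by the mean and the 2.5th/97.5th draw percentiles (the 95% UI).
Aggregation is population-weighted and exactly linear, so nested aggregation
(admin2 -> admin1 -> country) is consistent at machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from washmap.admin import AdminHierarchy
from washmap.spatial import DrawCube

MEAN_ANNUAL_CHANGE_SPAN = 18  # years spanned by the 2000-2017 study period
HIGH_ACCESS_THRESHOLD = 0.80
DOMINANT_THRESHOLD = 0.60

DOMINANT_LABELS = ("improved", "unimproved", "none", "mixed")
TRANSITIONS = ("substantial_upgrade", "incremental_upgrade", "other")


def aggregate_unit(
    cube: DrawCube, cells: np.ndarray, population: np.ndarray
) -> np.ndarray:
    """Population-weighted unit access per (year, draw).

    ``cells`` index into the cube's cell axis; ``population`` aligns with
    ``cells``.
    """
    w = np.asarray(population, float)
    if w.sum() <= 0:
        raise ValueError("unit has zero population")
    vals = cube.values[cells]  # (n_unit_cells, n_years, n_draws)
    return np.tensordot(w, vals, axes=(0, 0)) / w.sum()


def summarize_draws(draws: np.ndarray, axis: int = -1) -> dict[str, np.ndarray]:
    """Mean and central 95% interval over the draw axis."""
    return {
        "mean": draws.mean(axis=axis),
        "lower": np.percentile(draws, 2.5, axis=axis),
        "upper": np.percentile(draws, 97.5, axis=axis),
    }


def mean_annual_change(
    access_first: float | np.ndarray,
    access_last: float | np.ndarray,
    span: int = MEAN_ANNUAL_CHANGE_SPAN,
) -> float | np.ndarray:
    """Mean annual change in percentage points per year over the study span.

    Inputs are percentages (0-100); the default span of 18 years covers
    2000-2017 inclusive.
    """
    return (np.asarray(access_last, float) - np.asarray(access_first, float)) / span


def count_without_access(unit_draws: np.ndarray, population: float) -> np.ndarray:
    """Persons without access per draw: pop × (1 - access).  Interval bounds
    reverse order under this monotone decreasing transform."""
    return population * (1.0 - np.asarray(unit_draws, float))


def classify_dominant(
    improved: np.ndarray,
    unimproved: np.ndarray,
    none: np.ndarray,
    threshold: float = DOMINANT_THRESHOLD,
) -> np.ndarray:
    """Dominant facility class per draw: the group strictly exceeding the
    threshold (default 60%), else 'mixed'."""
    improved = np.asarray(improved, float)
    shares = np.stack([improved, np.asarray(unimproved, float), np.asarray(none, float)])
    if np.any(np.abs(shares.sum(axis=0) - 1.0) > 1e-6):
        raise ValueError("grouped shares must sum to 1")
    out = np.full(improved.shape, "mixed", dtype=object)
    for label, s in zip(("improved", "unimproved", "none"), shares):
        out[s > threshold] = label
    return out


def transition_type(label_2000: str, label_2017: str) -> str:
    """Transition typology between first- and last-year dominant classes:
    none -> improved is a substantial upgrade; none -> unimproved and
    unimproved -> improved are incremental; everything else 'other'."""
    for lab in (label_2000, label_2017):
        if lab not in DOMINANT_LABELS:
            raise ValueError(f"unknown dominant label {lab!r}")
    if label_2000 == "none" and label_2017 == "improved":
        return "substantial_upgrade"
    if (label_2000, label_2017) in (("none", "unimproved"), ("unimproved", "improved")):
        return "incremental_upgrade"
    return "other"


def high_access_share(
    unit_draws: np.ndarray, threshold: float = HIGH_ACCESS_THRESHOLD
) -> dict[str, float]:
    """Share of units at/above the high-access threshold, computed per draw
    then summarised.  ``unit_draws`` is (n_units, n_draws)."""
    shares = (np.asarray(unit_draws, float) >= threshold).mean(axis=0)
    s = summarize_draws(shares)
    return {k: float(v) for k, v in s.items()}


# --------------------------------------------------------------------------
# tabulated outputs


def unit_estimates_table(
    category_cubes: list[DrawCube],
    admin: AdminHierarchy,
    level: str,
    indicator_names: tuple[str, ...] = ("cat1", "cat2", "cat3", "cat4"),
) -> pd.DataFrame:
    """Per unit-year-indicator summary CSV rows.

    ``category_cubes`` hold the four recombined category surfaces over the
    same cells (typically one country's).
    """
    cube0 = category_cubes[0]
    cell_pos = {int(c): i for i, c in enumerate(cube0.cells)}
    rows = []
    for unit in admin.units(level):
        cells = [c for c in admin.cells_of(unit) if int(c) in cell_pos]
        if not cells:
            continue
        idx = np.array([cell_pos[int(c)] for c in cells])
        pop = admin.population[np.array(cells)]
        if pop.sum() <= 0:
            continue
        for name, cube in zip(indicator_names, category_cubes):
            draws = aggregate_unit(cube, idx, pop)  # (years, draws)
            s = summarize_draws(draws)
            unit_pop = float(pop.sum())
            nw_mean = count_without_access(draws, unit_pop).mean(axis=-1)
            for t, year in enumerate(cube.years):
                rows.append(
                    {
                        "unit_id": unit,
                        "level": level,
                        "indicator": name,
                        "year": year,
                        "mean": s["mean"][t],
                        "lower": s["lower"][t],
                        "upper": s["upper"][t],
                        "population": unit_pop,
                        "n_without_access_mean": nw_mean[t],
                        # monotone decreasing transform: bounds swap
                        "n_without_access_lower": unit_pop * (1.0 - s["upper"][t]),
                        "n_without_access_upper": unit_pop * (1.0 - s["lower"][t]),
                    }
                )
    return pd.DataFrame(rows)


def transitions_table(
    category_cubes: list[DrawCube],
    admin: AdminHierarchy,
    level: str = "admin2",
) -> pd.DataFrame:
    """Dominant-type labels in the first and last study year and the
    transition class, with draw-count uncertainty intervals.

    Improved groups categories 1+2; unimproved is category 3; none is
    category 4.  Labels reported are those of the draw-mean shares; per-draw
    classification yields the UI on counts of units per transition class.
    """
    cube0 = category_cubes[0]
    first, last = 0, len(cube0.years) - 1
    cell_pos = {int(c): i for i, c in enumerate(cube0.cells)}
    rows = []
    per_draw_transitions = []
    for unit in admin.units(level):
        cells = [c for c in admin.cells_of(unit) if int(c) in cell_pos]
        if not cells:
            continue
        idx = np.array([cell_pos[int(c)] for c in cells])
        pop = admin.population[np.array(cells)]
        if pop.sum() <= 0:
            continue
        grouped = {}
        for t in (first, last):
            cats = [aggregate_unit(c, idx, pop)[t] for c in category_cubes]  # 4 x draws
            grouped[t] = (cats[0] + cats[1], cats[2], cats[3])
        lab0 = classify_dominant(*[np.array([g.mean()]) for g in grouped[first]])[0]
        lab1 = classify_dominant(*[np.array([g.mean()]) for g in grouped[last]])[0]
        draws0 = classify_dominant(*grouped[first])
        draws1 = classify_dominant(*grouped[last])
        trans_draws = np.array(
            [transition_type(a, b) for a, b in zip(draws0, draws1)], dtype=object
        )
        per_draw_transitions.append(trans_draws)
        rows.append(
            {
                "unit_id": unit,
                "label_2000": lab0,
                "label_2017": lab1,
                "transition": transition_type(lab0, lab1),
            }
        )
    df = pd.DataFrame(rows)
    if per_draw_transitions:
        stacked = np.stack(per_draw_transitions)  # (units, draws)
        for tr in TRANSITIONS:
            counts = (stacked == tr).sum(axis=0)
            s = summarize_draws(counts.astype(float))
            df[f"n_{tr}_mean"] = s["mean"]
            df[f"n_{tr}_lower"] = s["lower"]
            df[f"n_{tr}_upper"] = s["upper"]
    return df
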