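"""Within-country geographical inequality in access.

The headline metric is the population-weighted Gini coefficient across
admin2 units,

    G = Σ_i Σ_j w_i w_j |x_i − x_j| / (2 (Σ_k w_k)² μ),

with μ the population-weighted mean access: 0 is perfect equality, 1 maximum
inequality.  Disparity metrics report the range from the highest- to the
lowest-access unit, the absolute gap (mean − min, percentage points) and the
relative ratio (mean / min, the "times lower" convention).  Units are
weighted by population by default; an unweighted variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class InequalityResult:
    country: str
    indicator: str
    year: int
    gini: float
    min_access: float
    max_access: float
    mean_access: float
    gap_pp: float
    ratio: float | None  # None when min access is 0 (undefined)

    def __post_init__(self) -> None:
        if not (0.0 <= self.gini <= 1.0 + 1e-12):
            raise ValueError("gini out of [0, 1]")
        if not (self.min_access - 1e-12 <= self.mean_access <= self.max_access + 1e-12):
            raise ValueError("mean access outside [min, max]")


def gini(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Population-weighted Gini of unit access proportions.

    Invariant to rescaling of the weights; requires a positive mean.
    """
    x = np.asarray(values, float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    mu = float((w * x).sum() / w.sum())
    if mu <= 0:
        raise ValueError("gini undefined: weighted mean access is zero")
    diff = np.abs(x[:, None] - x[None, :])
    num = float(w @ diff @ w)
    return num / (2.0 * w.sum() ** 2 * mu)


def disparity(
    country: str,
    indicator: str,
    year: int,
    values: np.ndarray,
    weights: np.ndarray | None = None,
) -> InequalityResult:
    """Range/gap/ratio disparity metrics plus the Gini for one country-year."""
    x = np.asarray(values, float)
    if len(x) < 2:
        raise ValueError("need >= 2 units for disparity metrics")
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    mean = float((w * x).sum() / w.sum())
    mn, mx = float(x.min()), float(x.max())
    ratio = None if mn <= 0 else mean / mn
    return InequalityResult(
        country=country,
        indicator=indicator,
        year=year,
        gini=gini(x, w),
        min_access=mn,
        max_access=mx,
        mean_access=mean,
        gap_pp=(mean - mn) * 100.0,
        ratio=ratio,
    )


def gini_threshold_counts(results: list[InequalityResult], threshold: float) -> int:
    """Number of countries whose Gini strictly exceeds the threshold."""
    return sum(1 for r in results if r.gini > threshold)


def inequality_table(results: list[InequalityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "country": r.country,
                "indicator": r.indicator,
                "year": r.year,
                "gini": r.gini,
                "min": r.min_access,
                "max": r.max_access,
                "mean": r.mean_access,
                "gap_pp": r.gap_pp,
                "ratio": np.nan if r.ratio is None else r.ratio,
            }
            for r in results
        ]
    )
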