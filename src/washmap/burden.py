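"""Comparative risk assessment: attributable and averted child deaths.

Exposure distributions over facility categories (crossed with household
water treatment for the water domain) are combined with relative risks of
diarrhoeal disease to give the population attributable fraction

    PAF = (RW - 1) / RW,      RW = Σ_i P_i · RR_i,

attributable under-5 diarrhoeal deaths D·PAF in the last study year, and
deaths averted by access changes since the first year via the counterfactual

    D_cf = D · RW_2000 / RW_2017,     averted = D_cf - D_2017,

which holds the cause-deleted mortality envelope fixed; negative averted
counts are deaths *caused* by worsening access.  Uncertainty propagates by
repeating every calculation for each posterior draw.

Risk ratios and treatment prevalences are user-supplied inputs (CSV); the
package ships a synthetic default table, not published risk estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RiskRatioTable:
    """Relative risks per exposure category; exactly one reference with
    RR = 1, all others >= 1."""

    domain: str
    exposure_ids: tuple[str, ...]
    rr: np.ndarray
    reference: str

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, float)
        if len(self.exposure_ids) != len(self.rr):
            raise ValueError("exposure ids and RRs must align")
        if self.reference not in self.exposure_ids:
            raise ValueError("reference category missing from exposure ids")
        if np.any(self.rr < 1.0):
            raise ValueError("all relative risks must be >= 1")
        ref_rr = self.rr[self.exposure_ids.index(self.reference)]
        if abs(ref_rr - 1.0) > 1e-12:
            raise ValueError("reference category must have RR = 1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, domain: str) -> "RiskRatioTable":
        sub = df[df["domain"] == domain]
        refs = sub[sub["is_reference"].astype(bool)]
        if len(refs) != 1:
            raise ValueError(f"{domain}: exactly one reference category required")
        return cls(
            domain=domain,
            exposure_ids=tuple(sub["exposure_id"]),
            rr=sub["rr"].to_numpy(float),
            reference=str(refs["exposure_id"].iloc[0]),
        )

    @classmethod
    def from_csv(cls, path: str | Path, domain: str) -> "RiskRatioTable":
        return cls.from_frame(pd.read_csv(path), domain)


WATER_EXPOSURE_IDS = tuple(
    f"{cat}_{tr}"
    for cat in ("piped", "other_improved", "unimproved", "surface")
    for tr in ("treated", "untreated")
)
SANITATION_EXPOSURE_IDS = ("sewer_septic", "other_improved", "unimproved", "open_defecation")


def build_water_exposure(category_probs: np.ndarray, treatment: float | np.ndarray) -> np.ndarray:
    """Water exposure distribution: facility category × {treated, untreated}
    under within-unit independence, ordered as :data:`WATER_EXPOSURE_IDS`.

    ``category_probs`` stacks p1..p4 on axis 0 (any trailing shape, e.g.
    draws); ``treatment`` is the household water-treatment prevalence.
    """
    p = np.asarray(category_probs, float)
    if p.shape[0] != 4:
        raise ValueError("category_probs must stack the 4 categories on axis 0")
    t = np.asarray(treatment, float)
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("treatment prevalence must lie in [0, 1]")
    out = np.stack([p[i // 2] * (t if i % 2 == 0 else (1.0 - t)) for i in range(8)])
    return out


def build_sanitation_exposure(category_probs: np.ndarray) -> np.ndarray:
    """Sanitation exposure equals the facility distribution."""
    p = np.asarray(category_probs, float)
    if p.shape[0] != 4:
        raise ValueError("category_probs must stack the 4 categories on axis 0")
    return p


def paf(exposure: np.ndarray, rr: RiskRatioTable) -> np.ndarray:
    """Population attributable fraction (ΣP·RR − 1)/ΣP·RR, in [0, 1).

    ``exposure`` stacks exposure categories on axis 0 in the table's order.
    """
    e = np.asarray(exposure, float)
    if e.shape[0] != len(rr.exposure_ids):
        raise ValueError(
            f"exposure has {e.shape[0]} categories, RR table has {len(rr.exposure_ids)}"
        )
    if np.any(e < 0):
        raise ValueError("exposure probabilities must be non-negative")
    sums = e.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValueError("exposure distribution must sum to 1")
    rw = np.tensordot(rr.rr, e, axes=(0, 0))
    return (rw - 1.0) / rw


def attributable_deaths(deaths: float | np.ndarray, paf_value: np.ndarray) -> np.ndarray:
    """Attributable deaths D·PAF; additive over units."""
    return np.asarray(deaths, float) * np.asarray(paf_value, float)


def averted_deaths(
    deaths_2017: float | np.ndarray,
    exposure_2000: np.ndarray,
    exposure_2017: np.ndarray,
    rr: RiskRatioTable,
) -> np.ndarray:
    """Deaths averted in the last year by access changes since the first.

    Counterfactual deaths scale observed deaths by RW_2000/RW_2017 (fixed
    cause-deleted envelope); negative values mean deaths caused.
    """
    rw0 = np.tensordot(rr.rr, np.asarray(exposure_2000, float), axes=(0, 0))
    rw1 = np.tensordot(rr.rr, np.asarray(exposure_2017, float), axes=(0, 0))
    d = np.asarray(deaths_2017, float)
    return d * rw0 / rw1 - d


def synthetic_risk_ratio_frame() -> pd.DataFrame:
    """A shipped synthetic default RR table (NOT published estimates): risk
    increases monotonically from the safest, treated categories to surface
    water / open defecation."""
    rows = []
    water_rr = {
        "piped_treated": 1.0,
        "piped_untreated": 1.3,
        "other_improved_treated": 1.4,
        "other_improved_untreated": 1.8,
        "unimproved_treated": 1.9,
        "unimproved_untreated": 2.4,
        "surface_treated": 2.6,
        "surface_untreated": 3.2,
    }
    for eid in WATER_EXPOSURE_IDS:
        rows.append(
            {
                "domain": "water",
                "exposure_id": eid,
                "rr": water_rr[eid],
                "is_reference": eid == "piped_treated",
            }
        )
    san_rr = {"sewer_septic": 1.0, "other_improved": 1.5, "unimproved": 2.2, "open_defecation": 3.0}
    for eid in SANITATION_EXPOSURE_IDS:
        rows.append(
            {
                "domain": "sanitation",
                "exposure_id": eid,
                "rr": san_rr[eid],
                "is_reference": eid == "sewer_septic",
            }
        )
    return pd.DataFrame(rows)
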