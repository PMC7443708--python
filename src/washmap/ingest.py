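"""Survey ingestion: facility-type categorisation and areal-to-point
conversion.

Free-text facility labels are mapped onto the two ordinal 4-category schemas
(water: piped / other improved / unimproved / surface water; sanitation:
sewer-septic / other improved / unimproved / open defecation) through an
editable CSV dictionary following the JMP standardised definitions, so
indicator updates do not require code changes.  Unknown labels are rejected,
never guessed.

Areal records are converted into population-weighted pseudo-point records:
the record's households are allocated across the polygon's cells proportional
to cell population with largest-remainder rounding, and category counts are
apportioned by controlled rounding so that both each pseudo-point's total and
every parent category count are conserved exactly.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import numpy as np

from washmap.admin import AdminHierarchy
from washmap.grids import RasterGrid
from washmap.records import SurveyRecord

DOMAINS = ("water", "sanitation")


class FacilityClassificationError(KeyError):
    """Raised for a facility label absent from the dictionary."""


def _default_dictionary_path():
    return resources.files("washmap.data") / "facility_labels.csv"


def load_label_dictionary(path: str | Path | None = None) -> dict[tuple[str, str], int]:
    """Load ``(domain, label) -> category`` from the dictionary CSV."""
    src = Path(path) if path is not None else _default_dictionary_path()
    mapping: dict[tuple[str, str], int] = {}
    with src.open() as fh:
        for row in csv.DictReader(fh):
            domain = row["domain"].strip().lower()
            label = row["label"].strip().lower()
            if domain not in DOMAINS:
                raise ValueError(f"unknown domain {domain!r} in dictionary")
            if not label:
                raise ValueError("empty facility label in dictionary")
            mapping[(domain, label)] = int(row["category"])
    return mapping


_DICTIONARY: dict[tuple[str, str], int] | None = None


def _dictionary() -> dict[tuple[str, str], int]:
    global _DICTIONARY
    if _DICTIONARY is None:
        _DICTIONARY = load_label_dictionary()
    return _DICTIONARY


def classify_facility(domain: str, label: str) -> int:
    """Ordinal category (1..4) for a facility label; case-insensitive."""
    if domain not in DOMAINS:
        raise ValueError(f"domain must be one of {DOMAINS}, got {domain!r}")
    key = label.strip().lower()
    if not key:
        raise FacilityClassificationError("empty facility label")
    try:
        return _dictionary()[(domain, key)]
    except KeyError:
        raise FacilityClassificationError(
            f"unmapped {domain} facility label: {label!r}"
        ) from None


def classify_water_facility(label: str) -> int:
    """1 piped, 2 other improved, 3 unimproved, 4 surface water."""
    return classify_facility("water", label)


def classify_sanitation_facility(label: str) -> int:
    """1 sewer/septic, 2 other improved, 3 unimproved, 4 open defecation."""
    return classify_facility("sanitation", label)


# --------------------------------------------------------------------------
# areal -> pseudo-point conversion


def largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``.

    Floors the exact shares and hands remaining units to the largest
    fractional parts; ties break toward the lower index, so the allocation is
    deterministic.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    shortfall = int(total - base.sum())
    if shortfall:
        # stable argsort => lower index wins ties on equal remainders
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:shortfall]] += 1
    return base


def _controlled_rounding(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Integer matrix with the given margins, close to the product expectation.

    Floors the expected matrix then assigns the remaining units greedily by
    descending fractional part among entries whose row and column still have
    slack.  Both margins are met exactly; fully deterministic.
    """
    R = np.asarray(row_totals, int)
    C = np.asarray(col_totals, int)
    total = int(R.sum())
    if total != int(C.sum()):
        raise ValueError("margins disagree")
    if total == 0:
        return np.zeros((len(R), len(C)), dtype=int)
    exact = np.outer(R, C).astype(float) / total
    M = np.floor(exact).astype(int)
    frac = exact - M
    r_slack = R - M.sum(axis=1)
    c_slack = C - M.sum(axis=0)
    order = np.argsort(-frac, axis=None, kind="stable")
    for flat in order:
        if r_slack.sum() == 0:
            break
        i, k = divmod(int(flat), len(C))
        if r_slack[i] > 0 and c_slack[k] > 0:
            M[i, k] += 1
            r_slack[i] -= 1
            c_slack[k] -= 1
    # greedy by fractional part can strand slack; finish with any legal cell
    while r_slack.sum() > 0:
        i = int(np.argmax(r_slack > 0))
        k = int(np.argmax(c_slack > 0))
        M[i, k] += 1
        r_slack[i] -= 1
        c_slack[k] -= 1
    return M


def resample_areal_to_points(
    record: SurveyRecord,
    population: RasterGrid,
    admin: AdminHierarchy,
) -> list[SurveyRecord]:
    """Split an areal record into population-weighted pseudo-point records.

    Cells allocated zero households are dropped; totals (N and each category
    count) are conserved exactly.
    """
    if record.source_type != "areal" or record.polygon is None:
        raise ValueError("record is not areal")
    cells = admin.cells_of(record.polygon)
    pop = population.flat()[cells]
    if pop.sum() <= 0:
        raise ValueError(f"polygon {record.polygon} has zero population")
    cell_n = largest_remainder(record.N, pop)
    counts = _controlled_rounding(cell_n, record.counts)
    out = []
    for j, (cell, n) in enumerate(zip(cells, cell_n)):
        if n == 0:
            continue
        out.append(
            SurveyRecord(
                record_id=f"{record.record_id}/p{j}",
                source_type="point",
                country=record.country,
                admin1=admin.unit_id("admin1", int(cell)),
                admin2=admin.unit_id("admin2", int(cell)),
                cell=int(cell),
                year=record.year,
                N=int(n),
                counts=counts[j],
            )
        )
    return out
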