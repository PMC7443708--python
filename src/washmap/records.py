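"""Survey records: one observation of household counts in the four ordered
facility categories, georeferenced either to a grid cell (point data) or to an
admin polygon (areal data)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CSV_COLUMNS = [
    "record_id",
    "source_type",
    "country",
    "admin1",
    "admin2",
    "cell_row",
    "cell_col",
    "polygon",
    "year",
    "N",
    "n_cat1",
    "n_cat2",
    "n_cat3",
    "n_cat4",
]


@dataclass
class SurveyRecord:
    """Category counts for one survey cluster or areal aggregate.

    Exactly one of ``cell`` (flat grid index, point data) and ``polygon``
    (admin unit id, areal data) is set; ``counts`` holds the four ordered
    category counts and must sum to ``N``.
    """

    record_id: str
    source_type: str  # "point" | "areal"
    country: str
    year: int
    N: int
    counts: np.ndarray
    cell: int | None = None
    polygon: str | None = None
    admin1: str | None = None
    admin2: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4,):
            raise ValueError("counts must hold the 4 ordered categories")
        if np.any(self.counts < 0):
            raise ValueError("negative category count")
        if int(self.counts.sum()) != self.N:
            raise ValueError(
                f"counts sum {int(self.counts.sum())} != N {self.N} in {self.record_id}"
            )
        if (self.cell is None) == (self.polygon is None):
            raise ValueError("exactly one of cell / polygon must be set")
        if self.source_type not in ("point", "areal"):
            raise ValueError(f"bad source_type {self.source_type!r}")


def records_to_frame(records: list[SurveyRecord], n_cols: int | None = None) -> pd.DataFrame:
    """Tabulate records in the survey CSV schema.

    ``n_cols`` (grid width) converts flat cell indices to (row, col); omit it
    for purely areal record sets.
    """
    rows = []
    for r in records:
        if r.cell is not None:
            if n_cols is None:
                raise ValueError("n_cols required to encode point records")
            cr, cc = divmod(int(r.cell), n_cols)
        else:
            cr = cc = ""
        rows.append(
            {
                "record_id": r.record_id,
                "source_type": r.source_type,
                "country": r.country,
                "admin1": r.admin1 or "",
                "admin2": r.admin2 or "",
                "cell_row": cr,
                "cell_col": cc,
                "polygon": r.polygon or "",
                "year": r.year,
                "N": r.N,
                "n_cat1": int(r.counts[0]),
                "n_cat2": int(r.counts[1]),
                "n_cat3": int(r.counts[2]),
                "n_cat4": int(r.counts[3]),
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame, n_cols: int | None = None) -> list[SurveyRecord]:
    records = []
    for _, row in df.iterrows():
        cell = None
        if row["source_type"] == "point":
            if n_cols is None:
                raise ValueError("n_cols required to decode point records")
            cell = int(row["cell_row"]) * n_cols + int(row["cell_col"])
        polygon = str(row["polygon"]) if row["source_type"] == "areal" else None
        records.append(
            SurveyRecord(
                record_id=str(row["record_id"]),
                source_type=str(row["source_type"]),
                country=str(row["country"]),
                admin1=str(row["admin1"]) or None,
                admin2=str(row["admin2"]) or None,
                cell=cell,
                polygon=polygon,
                year=int(row["year"]),
                N=int(row["N"]),
                counts=np.array(
                    [row["n_cat1"], row["n_cat2"], row["n_cat3"], row["n_cat4"]], int
                ),
            )
        )
    return records


def write_survey_csv(records: list[SurveyRecord], path: str | Path, n_cols: int | None = None) -> None:
    records_to_frame(records, n_cols).to_csv(path, index=False)


def read_survey_csv(path: str | Path, n_cols: int | None = None) -> list[SurveyRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    return frame_to_records(df, n_cols)
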