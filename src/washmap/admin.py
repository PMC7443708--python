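"""Administrative hierarchy: country -> admin1 -> admin2 over grid cells.

Unit ids are strings: ``"C3"`` (country 3), ``"C3A1"`` (its second
first-level unit), ``"C3A1S0"`` (a second-level unit).  Every cell belongs to
exactly one admin2 unit; membership of higher levels follows by prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LEVELS = ("country", "admin1", "admin2")


@dataclass
class AdminHierarchy:
    """Cell membership and per-cell population for a nested admin partition.

    Parameters
    ----------
    country, admin1, admin2
        Flat (row-major) integer-coded unit index per cell.
    population
        Persons per cell, non-negative.
    """

    country: np.ndarray
    admin1: np.ndarray
    admin2: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.population)
        for arr in (self.country, self.admin1, self.admin2):
            if len(arr) != n:
                raise ValueError("membership arrays must share one length")
        if np.any(self.population < 0):
            raise ValueError("population must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.population)

    def _codes(self, level: str) -> np.ndarray:
        if level not in LEVELS:
            raise ValueError(f"unknown admin level {level!r}")
        return {"country": self.country, "admin1": self.admin1, "admin2": self.admin2}[
            level
        ]

    def unit_id(self, level: str, cell: int) -> str:
        c, a, s = self.country[cell], self.admin1[cell], self.admin2[cell]
        if level == "country":
            return f"C{c}"
        if level == "admin1":
            return f"C{c}A{a}"
        return f"C{c}A{a}S{s}"

    def units(self, level: str) -> list[str]:
        """Sorted unique unit ids at a level."""
        cells = np.arange(self.n_cells)
        ids = sorted({self.unit_id(level, int(i)) for i in cells})
        return ids

    def cells_of(self, unit: str) -> np.ndarray:
        """Flat cell indices belonging to a unit (any level)."""
        level, codes = self._parse(unit)
        mask = np.ones(self.n_cells, dtype=bool)
        mask &= self.country == codes[0]
        if level != "country":
            mask &= self.admin1 == codes[1]
        if level == "admin2":
            mask &= self.admin2 == codes[2]
        cells = np.flatnonzero(mask)
        if cells.size == 0:
            raise KeyError(f"unknown admin unit {unit!r}")
        return cells

    def population_of(self, unit: str) -> float:
        return float(self.population[self.cells_of(unit)].sum())

    def level_of(self, unit: str) -> str:
        return self._parse(unit)[0]

    def parent(self, unit: str) -> str | None:
        level, codes = self._parse(unit)
        if level == "country":
            return None
        if level == "admin1":
            return f"C{codes[0]}"
        return f"C{codes[0]}A{codes[1]}"

    @staticmethod
    def _parse(unit: str) -> tuple[str, tuple[int, ...]]:
        try:
            if "S" in unit:
                c, rest = unit[1:].split("A")
                a, s = rest.split("S")
                return "admin2", (int(c), int(a), int(s))
            if "A" in unit:
                c, a = unit[1:].split("A")
                return "admin1", (int(c), int(a))
            return "country", (int(unit[1:]),)
        except (ValueError, IndexError) as exc:
            raise KeyError(f"malformed admin unit id {unit!r}") from exc

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": np.arange(self.n_cells),
                "country": self.country,
                "admin1": self.admin1,
                "admin2": self.admin2,
                "population": self.population,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AdminHierarchy":
        df = df.sort_values("cell")
        return cls(
            country=df["country"].to_numpy(int),
            admin1=df["admin1"].to_numpy(int),
            admin2=df["admin2"].to_numpy(int),
            population=df["population"].to_numpy(float),
        )
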