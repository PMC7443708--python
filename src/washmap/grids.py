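"""Planar raster grids.

Geometry is an abstract row-major grid: 0-based indices, origin at the
top-left cell centre, unit cell size by default.  Rasters carry either a
single band (``values.shape == (n_rows, n_cols)``) or one band per year
(``(n_bands, n_rows, n_cols)``).

Two on-disk dialects round-trip losslessly:

* a headered plain-text grid (``.asc``-style, one block per band), and
* a TIFF file written through :mod:`tifffile` with the grid metadata in a
  JSON sidecar-style ImageDescription tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class RasterGrid:
    """A gridded array of population, covariate, or probability values."""

    values: np.ndarray
    band_labels: list[int] | None = None
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("raster values must be 2-D or 3-D (bands, rows, cols)")
        if self.band_labels is not None and len(self.band_labels) != self.n_bands:
            raise ValueError("band_labels length does not match band count")

    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.values.shape[-2]

    @property
    def n_cols(self) -> int:
        return self.values.shape[-1]

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def band(self, label: int) -> np.ndarray:
        """Band by label (e.g. calendar year); 2-D rasters have one band."""
        if self.values.ndim == 2:
            return self.values
        if self.band_labels is None:
            return self.values[label]
        return self.values[self.band_labels.index(label)]

    def flat(self) -> np.ndarray:
        """Row-major flattened view: (n_cells,) or (n_bands, n_cells)."""
        if self.values.ndim == 2:
            return self.values.reshape(-1)
        return self.values.reshape(self.n_bands, -1)

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (row, col) coordinates of cell centres."""
        r0, c0 = self.origin
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        coords = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
        coords *= self.cell_size
        coords[:, 0] += r0
        coords[:, 1] += c0
        return coords

    # ------------------------------------------------------------------ I/O

    def _meta(self) -> dict:
        return {
            "n_bands": self.n_bands,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "band_labels": self.band_labels,
            "cell_size": self.cell_size,
            "origin": list(self.origin),
            "name": self.name,
        }

    def write_ascii(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# washmap raster v1\n")
            fh.write(json.dumps(self._meta()) + "\n")
            bands = self.values[None] if self.values.ndim == 2 else self.values
            for b in bands:
                for row in b:
                    fh.write(" ".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline()
            if not header.startswith("# washmap raster"):
                raise ValueError(f"{path} is not a washmap ascii raster")
            meta = json.loads(fh.readline())
            data = np.loadtxt(fh, dtype=float, ndmin=2)
        values = data.reshape(meta["n_bands"], meta["n_rows"], meta["n_cols"])
        if meta["n_bands"] == 1 and meta["band_labels"] is None:
            values = values[0]
        return cls(
            values=values,
            band_labels=meta["band_labels"],
            cell_size=meta["cell_size"],
            origin=tuple(meta["origin"]),
            name=meta["name"],
        )

    def write_tiff(self, path: str | Path) -> None:
        import tifffile

        bands = self.values[None] if self.values.ndim == 2 else self.values
        tifffile.imwrite(
            Path(path),
            bands.astype(np.float64),
            description=json.dumps(self._meta()),
            photometric="minisblack",
        )

    @classmethod
    def read_tiff(cls, path: str | Path) -> "RasterGrid":
        import tifffile

        with tifffile.TiffFile(Path(path)) as tf:
            meta = json.loads(tf.pages[0].description)
            values = tf.asarray().astype(float)
        values = values.reshape(meta["n_bands"], meta["n_rows"], meta["n_cols"])
        if meta["n_bands"] == 1 and meta["band_labels"] is None:
            values = values[0]
        return cls(
            values=values,
            band_labels=meta["band_labels"],
            cell_size=meta["cell_size"],
            origin=tuple(meta["origin"]),
            name=meta["name"],
        )
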