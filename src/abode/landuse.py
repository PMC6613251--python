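"""Gridded land-use classification used for dasymetric censoring.

Candidate dwelling points that fall in built-up commercial, industrial, or
institutional grid cells are not habitable dwellings and are removed before
population allocation.  The grid is a regular raster of integer class codes
(30 m cells by default), read from / written to the ESRI ASCII grid format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["UNKNOWN_CLASS", "LandUseGrid"]

#: Sentinel class for points outside the grid extent.
UNKNOWN_CLASS = "unknown"


@dataclass
class LandUseGrid:
    """Regular raster of land-use class codes.

    ``codes`` is stored in raster row order: row 0 is the northernmost row
    (as in the ASCII grid format).  ``(x0, y0)`` is the lower-left corner of
    the lower-left cell.  Cells are half-open in both axes,
    ``[x0 + j*s, x0 + (j+1)*s)``, so every in-extent point maps to exactly
    one cell.
    """

    x0: float
    y0: float
    cell_size: float
    codes: np.ndarray
    excluded_classes: frozenset[int] = field(default_factory=frozenset)
    nodata: int = -9999

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        self.excluded_classes = frozenset(int(c) for c in self.excluded_classes)

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.codes.shape[1]

    def cell_index(self, x: float, y: float) -> tuple[int, int] | None:
        """Raster (row, col) of the half-open cell containing (x, y), or None."""
        col = math.floor((x - self.x0) / self.cell_size)
        row_from_bottom = math.floor((y - self.y0) / self.cell_size)
        if not (0 <= col < self.n_cols and 0 <= row_from_bottom < self.n_rows):
            return None
        return self.n_rows - 1 - row_from_bottom, col

    def lookup(self, x: float, y: float) -> int | str:
        """Class code of the cell containing the point; ``"unknown"`` off-grid."""
        idx = self.cell_index(x, y)
        if idx is None:
            return UNKNOWN_CLASS
        code = int(self.codes[idx])
        return UNKNOWN_CLASS if code == self.nodata else code

    def lookup_many(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised lookup; off-grid and nodata cells return ``nodata``."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        rfb = np.floor((y - self.y0) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (rfb >= 0) & (rfb < self.n_rows)
        out = np.full(x.shape, self.nodata, dtype=int)
        rows = self.n_rows - 1 - rfb[inside]
        out[inside] = self.codes[rows, col[inside]]
        return out

    def is_excluded(self, x: float, y: float, keep_unknown: bool = True) -> bool:
        """Whether a point sits in an excluded (non-habitable) land-use cell.

        Off-grid points are retained by default (precautionary
        over-inclusion); set ``keep_unknown=False`` to drop them too.
        """
        cls = self.lookup(x, y)
        if cls == UNKNOWN_CLASS:
            return not keep_unknown
        return cls in self.excluded_classes

    # --- ESRI ASCII grid IO -------------------------------------------------

    @classmethod
    def from_ascii(
        cls, path: str | Path, excluded_classes: frozenset[int] | set[int] = frozenset()
    ) -> "LandUseGrid":
        """Read an ESRI ASCII grid (ncols/nrows/xllcorner/... header)."""
        path = Path(path)
        header: dict[str, float] = {}
        with path.open() as fh:
            pos = fh.tell()
            n_header = 0
            for _ in range(6):
                pos = fh.tell()
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in (
                    "ncols",
                    "nrows",
                    "xllcorner",
                    "yllcorner",
                    "cellsize",
                    "nodata_value",
                ):
                    header[parts[0].lower()] = float(parts[1])
                    n_header += 1
                else:
                    fh.seek(pos)
                    break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"{path}: missing ASCII grid header field {key!r}")
        codes = np.loadtxt(path, skiprows=n_header, dtype=int, ndmin=2)
        if codes.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError(
                f"{path}: data shape {codes.shape} does not match header "
                f"({int(header['nrows'])}, {int(header['ncols'])})"
            )
        return cls(
            x0=header["xllcorner"],
            y0=header["yllcorner"],
            cell_size=header["cellsize"],
            codes=codes,
            excluded_classes=frozenset(excluded_classes),
            nodata=int(header.get("nodata_value", -9999)),
        )

    def to_ascii(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {self.x0:.6f}\n")
            fh.write(f"yllcorner {self.y0:.6f}\n")
            fh.write(f"cellsize {self.cell_size:.6f}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            for row in self.codes:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
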