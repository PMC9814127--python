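"""Equal-area density grids and in situ / ex situ gap cells.

Record densities are compared on a grid of 10 km × 10 km cells.  For
real-world (lon/lat) inputs the grid lives in ETRS89-LAEA (EPSG:3035), the
projection underlying the standard European reference grid, with the
origin fixed at projected (0, 0) and cells aligned to 10 000 m multiples —
this reproduces the geometry of the published reference grid sheets
without shipping them.  Synthetic planar worlds use an identity projection
with km units and a 10 km cell.

Cells are half-open squares ``[x, x+s) × [y, y+s)``: a point on a shared
edge belongs to the higher-index cell only, so every point lands in
exactly one cell.

A *gap cell* holds at least one in situ record and no ex situ record —
a place where wild populations exist but nothing has been collected into
genebanks.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ConfigurationError, ValidationError
from .occurrence_io import OccurrenceRecord
from .projection import laea_forward


@dataclass(frozen=True)
class Grid:
    """Origin-aligned equal-area grid covering a projected extent."""

    x0: float          # lower-left corner, multiple of cell_size
    y0: float
    n_cols: int
    n_rows: int
    cell_size: float = 10_000.0

    @property
    def x1(self) -> float:
        return self.x0 + self.n_cols * self.cell_size

    @property
    def y1(self) -> float:
        return self.y0 + self.n_rows * self.cell_size

    def cell_of(self, x: float, y: float) -> Optional[tuple[int, int]]:
        """(col, row) of the half-open cell containing the point, or None."""
        if not (self.x0 <= x < self.x1 and self.y0 <= y < self.y1):
            return None
        col = int(math.floor((x - self.x0) / self.cell_size))
        row = int(math.floor((y - self.y0) / self.cell_size))
        return col, row

    def cell_bounds(self, col: int, row: int) -> tuple[float, float, float, float]:
        s = self.cell_size
        return (self.x0 + col * s, self.y0 + row * s,
                self.x0 + (col + 1) * s, self.y0 + (row + 1) * s)


def build_grid(extent: tuple[float, float, float, float],
               cell_size: float = 10_000.0) -> Grid:
    """Grid snapped outward so origin-aligned cells cover the whole extent.

    ``extent`` is (xmin, ymin, xmax, ymax) in projected coordinates.  The
    grid origin is the global projected (0, 0); cell corners sit on
    multiples of ``cell_size``.
    """
    if cell_size <= 0:
        raise ConfigurationError("cell size must be positive")
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ConfigurationError("degenerate extent")
    x0 = math.floor(xmin / cell_size) * cell_size
    y0 = math.floor(ymin / cell_size) * cell_size
    n_cols = int(math.ceil((xmax - x0) / cell_size))
    n_rows = int(math.ceil((ymax - y0) / cell_size))
    # a point exactly on the upper extent edge still needs a (half-open) cell
    if x0 + n_cols * cell_size <= xmax:
        n_cols += 1
    if y0 + n_rows * cell_size <= ymax:
        n_rows += 1
    return Grid(x0, y0, n_cols, n_rows, cell_size)


@dataclass
class GridCounts:
    grid: Grid
    side: str                      # "in_situ" | "ex_situ"
    cells: Counter = field(default_factory=Counter)   # (col, row) -> n
    n_outside_extent: int = 0
    species_per_cell: dict = field(default_factory=dict)  # (col, row) -> Counter

    @property
    def total_in_extent(self) -> int:
        return sum(self.cells.values())

    def occupied(self) -> list[tuple[int, int]]:
        return sorted(k for k, v in self.cells.items() if v > 0)


def project_point(lon: float, lat: float, planar: bool) -> tuple[float, float]:
    """Projected coordinates: EPSG:3035 metres, or identity for planar worlds."""
    if planar:
        return lon, lat
    return laea_forward(lon, lat)


def count_points(grid: Grid,
                 records: Iterable[OccurrenceRecord],
                 side: str,
                 planar: bool = False) -> GridCounts:
    """Per-cell record counts for one conservation side.

    Records of the other side, or without coordinates, are ignored;
    in-side records falling outside the grid extent are tallied in
    ``n_outside_extent``.
    """
    counts = GridCounts(grid, side)
    for r in records:
        if r.conservation_side != side or not r.has_coords:
            continue
        x, y = project_point(r.lon, r.lat, planar)
        cell = grid.cell_of(x, y)
        if cell is None:
            counts.n_outside_extent += 1
            continue
        counts.cells[cell] += 1
        counts.species_per_cell.setdefault(cell, Counter())[r.taxon] += 1
    return counts


def density_class_proportions(counts: GridCounts) -> dict[int, float]:
    """Among occupied cells, the fraction holding exactly k records.

    Undefined (empty dict is *not* returned — callers treat the quantity
    as absent) when no cell is occupied.
    """
    occupied = [n for n in counts.cells.values() if n > 0]
    if not occupied:
        raise ValidationError("no occupied cells: density classes undefined")
    n = len(occupied)
    hist = Counter(occupied)
    return {k: hist[k] / n for k in sorted(hist)}


@dataclass
class GapCell:
    col: int
    row: int
    n_in_situ: int
    dominant_species: Optional[str]


def gap_cells(in_counts: GridCounts,
              ex_counts: GridCounts) -> tuple[list[GapCell], dict]:
    """Cells with in situ presence and no ex situ record, plus density deltas.

    Returns ``(gaps, differences)`` where gaps are sorted by decreasing in
    situ count (then by cell index) and ``differences`` maps every occupied
    cell to ``n_in_situ - n_ex_situ``.
    """
    if in_counts.grid != ex_counts.grid:
        raise ValidationError("grid mismatch between in situ and ex situ counts")
    gaps = []
    for cell, n_in in in_counts.cells.items():
        if n_in >= 1 and ex_counts.cells.get(cell, 0) == 0:
            species = in_counts.species_per_cell.get(cell)
            dominant = None
            if species:
                dominant = min(species.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            gaps.append(GapCell(cell[0], cell[1], n_in, dominant))
    gaps.sort(key=lambda g: (-g.n_in_situ, g.col, g.row))
    occupied = set(in_counts.cells) | set(ex_counts.cells)
    differences = {cell: in_counts.cells.get(cell, 0) - ex_counts.cells.get(cell, 0)
                   for cell in sorted(occupied)}
    return gaps, differences


def write_grid_counts(in_counts: GridCounts, ex_counts: GridCounts, path) -> None:
    """Delimited-text export: col, row, x0, y0, n_in_situ, n_ex_situ, gap flag."""
    from pathlib import Path
    grid = in_counts.grid
    lines = ["col,row,x0,y0,n_in_situ,n_ex_situ,gap"]
    for cell in sorted(set(in_counts.cells) | set(ex_counts.cells)):
        x0, y0, _, _ = grid.cell_bounds(*cell)
        n_in = in_counts.cells.get(cell, 0)
        n_ex = ex_counts.cells.get(cell, 0)
        gap = 1 if n_in >= 1 and n_ex == 0 else 0
        lines.append(f"{cell[0]},{cell[1]},{x0:g},{y0:g},{n_in},{n_ex},{gap}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
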