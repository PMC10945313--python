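"""Gridded domain containers shared by every pipeline stage.

All grids use 0-based (row, col) indexing with row 0 at the top. Cell
footprints are stored as integer ``(n, 2)`` arrays of ``(row, col)``
coordinates; boolean per-cell fields are 2-D arrays of the grid shape.
``cell_area`` is a uniform scalar in km² (default 25 km², the area of a
~5 km cell at 2.5 arcmin resolution near the equator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CELL_AREA_KM2 = 25.0

#: Protected-area management categories: strictly protected areas,
#: sustainable use areas, indigenous territories.
PA_CATEGORIES = ("SPA", "SUA", "IT")


@dataclass
class GridGeometry:
    """Georeferencing of a north-up regular grid (ESRI ASCII grid convention).

    ``x_ll``/``y_ll`` locate the lower-left corner; cell (r, c) spans
    ``[x_ll + c*cs, x_ll + (c+1)*cs) x [y_ll + (n_rows-1-r)*cs, ...)``.
    """

    n_rows: int
    n_cols: int
    x_ll: float = 0.0
    y_ll: float = 0.0
    cell_size: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.x_ll + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y_ll + (self.n_rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Containing cell of each point, half-open intervals; may fall off-grid."""
        col = np.floor((np.asarray(x, dtype=float) - self.x_ll) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor(
            (np.asarray(y, dtype=float) - self.y_ll) / self.cell_size
        ).astype(int)
        return row, col

    def __eq__(self, other) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.isclose(self.x_ll, other.x_ll)
            and np.isclose(self.y_ll, other.y_ll)
            and np.isclose(self.cell_size, other.cell_size)
        )


def as_cell_array(cells) -> np.ndarray:
    """Normalize a collection of (row, col) pairs to a unique, sorted (n, 2) int array."""
    arr = np.asarray(sorted(set(map(tuple, cells))), dtype=int)
    return arr.reshape(-1, 2)


def cells_to_mask(cells: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if len(cells):
        mask[cells[:, 0], cells[:, 1]] = True
    return mask


@dataclass
class ClimateStack:
    """Multi-layer gridded environment for one climate scenario."""

    layers: np.ndarray  # (n_vars, rows, cols)
    var_names: list[str]
    scenario_id: str
    valid_mask: np.ndarray  # (rows, cols) bool
    cell_area: float = DEFAULT_CELL_AREA_KM2
    geometry: GridGeometry | None = None

    def __post_init__(self):
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must be a (n_vars, rows, cols) array")
        if self.layers.shape[0] != len(self.var_names):
            raise ValueError("one name per layer required")
        if self.valid_mask.shape != self.grid_shape:
            raise ValueError("valid_mask shape must match layers")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if np.isnan(self.layers[:, self.valid_mask]).any():
            raise ValueError("missing values inside valid_mask")
        if self.geometry is None:
            self.geometry = GridGeometry(*self.grid_shape)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.layers.shape[1:]

    @property
    def n_vars(self) -> int:
        return self.layers.shape[0]


@dataclass
class VirtualSpecies:
    """Simulated taxon with a known environment-suitability relationship."""

    taxon_id: str
    niche_params: dict[str, tuple[float, float]]  # var -> (optimum, breadth)
    true_suitability: np.ndarray  # (rows, cols) in [0, 1]
    true_range: np.ndarray  # (rows, cols) bool
    endemism_region: np.ndarray  # (rows, cols) bool
    range_cut: float


@dataclass
class OccurrenceSet:
    """Unique presence cells for one taxon."""

    taxon_id: str
    cells: np.ndarray  # (n, 2) unique (row, col)

    def __post_init__(self):
        self.cells = as_cell_array(self.cells)

    @property
    def n_unique(self) -> int:
        return len(self.cells)


@dataclass
class ProtectedArea:
    pa_id: str
    category: str  # SPA | SUA | IT
    footprint: np.ndarray  # (n, 2) cells

    def __post_init__(self):
        self.footprint = as_cell_array(self.footprint)
        if len(self.footprint) == 0:
            raise ValueError(f"PA {self.pa_id}: empty footprint")
        if self.category not in PA_CATEGORIES:
            raise ValueError(f"PA {self.pa_id}: unknown category {self.category!r}")


@dataclass
class ProtectedAreaSet:
    areas: list[ProtectedArea] = field(default_factory=list)

    def __post_init__(self):
        ids = [a.pa_id for a in self.areas]
        if len(set(ids)) != len(ids):
            raise ValueError("pa_id values must be unique")

    def __len__(self) -> int:
        return len(self.areas)

    def __iter__(self):
        return iter(self.areas)

    def subset(self, categories) -> "ProtectedAreaSet":
        cats = set(categories)
        return ProtectedAreaSet([a for a in self.areas if a.category in cats])

    def union_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Cell-level OR of all footprints (overlaps counted once)."""
        mask = np.zeros(shape, dtype=bool)
        for a in self.areas:
            mask[a.footprint[:, 0], a.footprint[:, 1]] = True
        return mask


@dataclass
class LandCoverGrid:
    """Categorical land-cover grid; ``forest_codes`` mark habitat classes."""

    category: np.ndarray  # (rows, cols) int
    forest_codes: frozenset[int]
    geometry: GridGeometry | None = None

    def __post_init__(self):
        self.category = np.asarray(self.category, dtype=int)
        self.forest_codes = frozenset(int(c) for c in self.forest_codes)
        if self.geometry is None:
            self.geometry = GridGeometry(*self.category.shape)

    @property
    def forest_mask(self) -> np.ndarray:
        return np.isin(self.category, list(self.forest_codes))
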