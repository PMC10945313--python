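"""Binarization, habitat masking, area change and richness stacking.

Continuous ensemble suitability is cut into a presence/absence range at the
threshold that maximizes the Jaccard similarity between prediction and the
evaluation presences/pseudo-absences. The per-taxon threshold is selected
once on present-scenario data and reused for that taxon's future scenarios,
keeping ranges comparable through time. Ranges can then be intersected with
forest land-cover classes, restricted to the present range (floodplain
specialists), differenced into percent area change, and stacked cell-wise
into richness maps.

Cell-wise comparisons use >= — a cell exactly at the threshold counts as
suitable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import DEFAULT_CELL_AREA_KM2, LandCoverGrid
from .sdm import jaccard

__all__ = [
    "BinaryRange",
    "RichnessMap",
    "select_threshold",
    "binarize",
    "apply_forest_mask",
    "restrict_future_to_present",
    "area_change",
    "stack_richness",
]

#: Percent loss beyond which a taxon is reported as retaining no suitable area.
TOTAL_LOSS_PCT = 99.0


@dataclass
class BinaryRange:
    taxon_id: str
    scenario_id: str
    cells: np.ndarray  # (rows, cols) bool
    threshold_used: float
    cell_area: float = DEFAULT_CELL_AREA_KM2

    @property
    def n_cells(self) -> int:
        return int(np.count_nonzero(self.cells))

    @property
    def area_km2(self) -> float:
        return self.n_cells * self.cell_area

    @property
    def is_empty(self) -> bool:
        return self.n_cells == 0


@dataclass
class RichnessMap:
    scenario_id: str
    richness: np.ndarray  # (rows, cols) int
    taxa_included: list[str]


def select_threshold(suitability: np.ndarray, presence_cells: np.ndarray, absence_cells: np.ndarray) -> float:
    """Jaccard-maximizing suitability threshold over the evaluation cells.

    Candidates are the unique suitability values at the presence and
    pseudo-absence cells; ties in Jaccard are broken toward the smallest
    threshold. A constant surface admits only itself as threshold.
    """
    if len(presence_cells) == 0 or len(absence_cells) == 0:
        raise ValueError("need non-empty presence and absence cell sets")
    cells = np.vstack([presence_cells, absence_cells])
    vals = suitability[cells[:, 0], cells[:, 1]]
    labels = np.zeros(len(cells), dtype=bool)
    labels[: len(presence_cells)] = True
    cand = np.unique(vals)
    if len(cand) == 1:
        warnings.warn("constant suitability at evaluation cells; returning that value")
        return float(cand[0])
    best_j, best_t = -1.0, None
    for t in cand:
        j = jaccard(vals >= t, labels)
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def binarize(
    suitability: np.ndarray,
    threshold: float,
    taxon_id: str = "",
    scenario_id: str = "",
    valid_mask: np.ndarray | None = None,
    cell_area: float = DEFAULT_CELL_AREA_KM2,
) -> BinaryRange:
    """Cell true iff suitability >= threshold (NaN cells are never suitable)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    with np.errstate(invalid="ignore"):
        cells = np.asarray(suitability) >= threshold
    cells &= ~np.isnan(suitability)
    if valid_mask is not None:
        cells &= valid_mask
    return BinaryRange(taxon_id, scenario_id, cells, threshold, cell_area)


def apply_forest_mask(rng: BinaryRange, lc: LandCoverGrid) -> BinaryRange:
    """Keep only range cells whose land-cover code is a forest (habitat) class."""
    if lc.category.shape != rng.cells.shape:
        raise ValueError(
            f"land-cover shape {lc.category.shape} does not match range {rng.cells.shape}"
        )
    return BinaryRange(
        rng.taxon_id, rng.scenario_id, rng.cells & lc.forest_mask, rng.threshold_used, rng.cell_area
    )


def restrict_future_to_present(future: BinaryRange, present: BinaryRange) -> BinaryRange:
    """Clip a future range to the present range (floodplain-restricted taxa)."""
    if future.cells.shape != present.cells.shape:
        raise ValueError("grid shapes differ")
    if future.taxon_id != present.taxon_id:
        raise ValueError("ranges belong to different taxa")
    return BinaryRange(
        future.taxon_id,
        future.scenario_id,
        future.cells & present.cells,
        future.threshold_used,
        future.cell_area,
    )


def area_change(present: BinaryRange, future: BinaryRange) -> dict:
    """Percent change in range area from present to future (losses negative).

    A loss above 99% is flagged ``total_loss`` — the taxon effectively
    retains no suitable area.
    """
    if present.area_km2 <= 0:
        raise ValueError("present range area is zero; percent change undefined")
    pct = 100.0 * (future.area_km2 - present.area_km2) / present.area_km2
    return {
        "taxon_id": present.taxon_id,
        "scenario": future.scenario_id,
        "present_km2": present.area_km2,
        "future_km2": future.area_km2,
        "pct_change": pct,
        "total_loss": pct < -TOTAL_LOSS_PCT,
    }


def stack_richness(ranges: list[BinaryRange], grid_shape: tuple[int, int] | None = None) -> RichnessMap:
    """Stacked distribution model: per-cell count of taxa whose range covers the cell."""
    if not ranges:
        if grid_shape is None:
            raise ValueError("grid_shape required for an empty range list")
        return RichnessMap("", np.zeros(grid_shape, dtype=int), [])
    scenarios = {r.scenario_id for r in ranges}
    if len(scenarios) > 1:
        raise ValueError(f"ranges mix scenarios: {sorted(scenarios)}")
    shapes = {r.cells.shape for r in ranges}
    if len(shapes) > 1:
        raise ValueError("ranges are on different grids")
    rich = np.sum([r.cells for r in ranges], axis=0).astype(int)
    return RichnessMap(ranges[0].scenario_id, rich, [r.taxon_id for r in ranges])
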