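"""Synthetic landscapes, virtual species, occurrences, protected areas and land cover.

The generators emulate the statistical structure the downstream analysis
assumes — spatially autocorrelated climate surfaces, taxa whose suitability
is a known function of that climate, occurrence samples of realistic size,
and categorized protected-area footprints — so every stage of the pipeline
can be exercised and validated against known truth without external data.

Spatial autocorrelation is produced by smoothing white noise with a Gaussian
kernel of a stated scale (in cells) and re-standardizing. Virtual-species
suitability follows the standard virtual-species convention: independent
Gaussian response curves per variable, multiplied and rescaled to a maximum
of one.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .grids import (
    DEFAULT_CELL_AREA_KM2,
    PA_CATEGORIES,
    ClimateStack,
    LandCoverGrid,
    OccurrenceSet,
    ProtectedArea,
    ProtectedAreaSet,
    VirtualSpecies,
    as_cell_array,
)

__all__ = [
    "generate_landscape",
    "generate_future",
    "generate_virtual_species",
    "sample_occurrences",
    "generate_protected_areas",
    "generate_landcover",
]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Spatially autocorrelated field: Gaussian-smoothed white noise, unit-ish variance."""
    noise = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    return field


def _standardize(layer: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = layer[mask]
    sd = vals.std()
    if sd == 0:
        return layer - vals.mean()
    return (layer - vals.mean()) / sd


def generate_landscape(
    seed: int,
    grid_shape: tuple[int, int] = (50, 50),
    n_vars: int = 6,
    autocorr_scale: float = 5.0,
    scenario_id: str = "present",
    cell_area: float = DEFAULT_CELL_AREA_KM2,
) -> ClimateStack:
    """Generate a stack of autocorrelated climate layers, standardized over valid cells.

    Parameters
    ----------
    autocorr_scale
        Gaussian smoothing sigma in cells; larger values give smoother,
        more strongly autocorrelated surfaces.
    """
    rows, cols = grid_shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"grid_shape must be positive, got {grid_shape}")
    if n_vars < 2:
        raise ValueError("n_vars must be >= 2")
    if autocorr_scale <= 0:
        raise ValueError("autocorr_scale must be > 0")
    rng = np.random.default_rng(seed)
    valid = np.ones(grid_shape, dtype=bool)
    layers = np.empty((n_vars, rows, cols))
    for i in range(n_vars):
        layers[i] = _standardize(_smooth_field(rng, grid_shape, autocorr_scale), valid)
    names = [f"clim_{i + 1}" for i in range(n_vars)]
    return ClimateStack(layers, names, scenario_id, valid, cell_area=cell_area)


def generate_future(
    present: ClimateStack,
    shift,
    noise_sd: float = 0.0,
    seed: int = 0,
    scenario_id: str = "future",
    autocorr_scale: float = 5.0,
) -> ClimateStack:
    """Future scenario = present + per-variable shift + autocorrelated noise.

    ``shift`` has one entry per layer (e.g. a warming offset on the
    temperature-like axes); ``noise_sd`` sets the standard deviation of the
    added autocorrelated perturbation.
    """
    shift = np.asarray(shift, dtype=float)
    if shift.shape != (present.n_vars,):
        raise ValueError(
            f"shift must have one entry per layer ({present.n_vars}), got shape {shift.shape}"
        )
    rng = np.random.default_rng(seed)
    layers = present.layers + shift[:, None, None]
    if noise_sd > 0:
        for i in range(present.n_vars):
            field = _smooth_field(rng, present.grid_shape, autocorr_scale)
            sd = field[present.valid_mask].std()
            layers[i] += noise_sd * (field - field[present.valid_mask].mean()) / sd
    return ClimateStack(
        layers,
        list(present.var_names),
        scenario_id,
        present.valid_mask.copy(),
        cell_area=present.cell_area,
        geometry=present.geometry,
    )


def generate_virtual_species(
    stack: ClimateStack,
    niche_params: dict[str, tuple[float, float]],
    range_cut: float = 0.5,
    taxon_id: str = "virtual_sp",
    endemism_margin: int = 5,
) -> VirtualSpecies:
    """Virtual species from independent Gaussian response curves.

    suitability(cell) = prod_v exp(-(x_v - opt_v)^2 / (2 * breadth_v^2)),
    rescaled so the best valid cell scores 1. The true range is the set of
    valid cells at or above ``range_cut``. The endemism region is the
    bounding box of the true range dilated by ``endemism_margin`` cells —
    a stand-in for the biogeographic subregion a taxon is calibrated in.
    """
    missing = [v for v in niche_params if v not in stack.var_names]
    if missing:
        raise ValueError(f"niche_params reference unknown layers: {missing}")
    log_suit = np.zeros(stack.grid_shape)
    for var, (opt, breadth) in niche_params.items():
        x = stack.layers[stack.var_names.index(var)]
        log_suit -= (x - opt) ** 2 / (2.0 * breadth**2)
    suit = np.exp(log_suit - log_suit[stack.valid_mask].max())
    suit[~stack.valid_mask] = 0.0
    true_range = (suit >= range_cut) & stack.valid_mask
    if not true_range.any():
        warnings.warn(f"{taxon_id}: empty true range at range_cut={range_cut}")
        endemism = stack.valid_mask.copy()
    else:
        rws, cls = np.nonzero(true_range)
        r0 = max(rws.min() - endemism_margin, 0)
        r1 = min(rws.max() + endemism_margin + 1, stack.grid_shape[0])
        c0 = max(cls.min() - endemism_margin, 0)
        c1 = min(cls.max() + endemism_margin + 1, stack.grid_shape[1])
        endemism = np.zeros(stack.grid_shape, dtype=bool)
        endemism[r0:r1, c0:c1] = True
        endemism &= stack.valid_mask
    return VirtualSpecies(taxon_id, dict(niche_params), suit, true_range, endemism, range_cut)


def sample_occurrences(species: VirtualSpecies, n: int, seed: int) -> OccurrenceSet:
    """Sample ``n`` unique presence cells, probability proportional to suitability."""
    cells = np.argwhere(species.true_range)
    if n > len(cells):
        raise ValueError(
            f"{species.taxon_id}: requested {n} occurrences but true range has "
            f"only {len(cells)} cells"
        )
    p = species.true_suitability[cells[:, 0], cells[:, 1]]
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cells), size=n, replace=False, p=p)
    return OccurrenceSet(species.taxon_id, cells[idx])


def generate_protected_areas(
    grid_shape: tuple[int, int],
    n_areas: int = 347,
    size_range: tuple[int, int] = (2, 8),
    category_weights: dict[str, float] | None = None,
    seed: int = 0,
    max_tries: int = 50,
) -> ProtectedAreaSet:
    """Rectangular PA footprints placed uniformly at random, fully inside the grid.

    ``size_range`` bounds each rectangle's side length in cells; categories
    are drawn independently with the given weights (default uniform over
    SPA/SUA/IT). The default count of 347 areas mirrors a realistic
    biome-wide PA network size.
    """
    if n_areas < 1:
        raise ValueError("n_areas must be >= 1")
    rows, cols = grid_shape
    if category_weights is None:
        category_weights = {c: 1.0 for c in PA_CATEGORIES}
    cats = list(category_weights)
    w = np.array([category_weights[c] for c in cats], dtype=float)
    w = w / w.sum()
    lo, hi = size_range
    rng = np.random.default_rng(seed)
    areas: list[ProtectedArea] = []
    for i in range(n_areas):
        placed = False
        for _ in range(max_tries):
            h = int(rng.integers(lo, hi + 1))
            ww = int(rng.integers(lo, hi + 1))
            if h > rows or ww > cols:
                continue
            r0 = int(rng.integers(0, rows - h + 1))
            c0 = int(rng.integers(0, cols - ww + 1))
            rr, cc = np.mgrid[r0 : r0 + h, c0 : c0 + ww]
            cat = cats[int(rng.choice(len(cats), p=w))]
            areas.append(
                ProtectedArea(f"PA{i + 1:04d}", cat, np.column_stack([rr.ravel(), cc.ravel()]))
            )
            placed = True
            break
        if not placed:
            warnings.warn(f"PA {i + 1}: no fitting footprint after {max_tries} tries; skipped")
    return ProtectedAreaSet(areas)


def generate_landcover(
    grid_shape: tuple[int, int],
    forest_fraction: float = 0.7,
    autocorr_scale: float = 5.0,
    seed: int = 0,
) -> LandCoverGrid:
    """Spatially clumped categorical land cover with a target forest share.

    An autocorrelated latent field is thresholded at the (1 - forest_fraction)
    quantile, so the realized forest share matches the target up to quantile
    discreteness. Non-forest cells are split into two categories (grassland /
    anthropic) along the same latent field. Codes: 1 = forest, 2 = grassland,
    3 = anthropic.
    """
    if not 0.0 <= forest_fraction <= 1.0:
        raise ValueError("forest_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    field = _smooth_field(rng, grid_shape, autocorr_scale)
    cat = np.full(grid_shape, 2, dtype=int)
    if forest_fraction >= 1.0:
        cat[:] = 1
    elif forest_fraction > 0.0:
        cut = np.quantile(field, 1.0 - forest_fraction)
        cat[field >= cut] = 1
    nonforest = cat != 1
    if nonforest.any():
        mid = np.median(field[nonforest])
        cat[nonforest & (field < mid)] = 3
    return LandCoverGrid(cat, frozenset({1}))
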