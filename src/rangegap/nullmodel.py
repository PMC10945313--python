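"""Null-model test of protected-area effectiveness for richness.

A protected area is effective if the mean taxon richness of its cells
exceeds what an identically shaped area would capture by chance. The null
distribution comes from relocating the footprint uniformly at random within
the study area — translation only, preserving size, shape and orientation —
999 times (by default) and recording the relocated mean richness. The PA is
flagged effective when the observed mean is strictly greater than the null
value in at least 95% of randomizations; ties count against effectiveness.

Alongside the counting rule, an add-one permutation p-value
``(1 + #{null >= observed}) / (1 + n)`` is reported; it can never be zero,
so the two can disagree only exactly at the boundary.

Each PA draws from its own seed-derived random stream, making per-PA
results reproducible and independent of processing order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from math import ceil

import numpy as np

from .grids import ProtectedArea, ProtectedAreaSet
from .postprocess import RichnessMap

__all__ = [
    "EffectivenessResult",
    "mean_richness_in",
    "relocate_footprint",
    "effectiveness_test",
    "run_effectiveness_tests",
    "summarize_effectiveness",
]

DEFAULT_N_RANDOMIZATIONS = 999
MAX_RELOCATION_ATTEMPTS = 10_000


@dataclass
class EffectivenessResult:
    pa_id: str
    category: str
    scenario_id: str
    observed_mean_richness: float
    null_values: np.ndarray
    n_observed_greater: int
    p_value: float
    effective: bool
    untestable: bool = False


def mean_richness_in(footprint: np.ndarray, richness: RichnessMap | np.ndarray) -> float:
    """Arithmetic mean richness over the footprint cells."""
    if len(footprint) == 0:
        raise ValueError("footprint is empty")
    grid = richness.richness if isinstance(richness, RichnessMap) else np.asarray(richness)
    return float(grid[footprint[:, 0], footprint[:, 1]].mean())


def _pa_rng(seed: int, pa_id: str) -> np.random.Generator:
    """Independent, order-free stream per PA: global seed + stable id hash."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(pa_id.encode())]))


def _draw_offsets(
    footprint: np.ndarray,
    study_mask: np.ndarray,
    rng: np.random.Generator,
    n_needed: int,
    max_attempts: int = MAX_RELOCATION_ATTEMPTS,
) -> np.ndarray | None:
    """Accepted (Δrow, Δcol) translations keeping every cell inside study_mask."""
    rows, cols = study_mask.shape
    r, c = footprint[:, 0], footprint[:, 1]
    r0, r1 = r.min(), r.max()
    c0, c1 = c.min(), c.max()
    # admissible translation window so the bounding box stays on-grid
    dr_lo, dr_hi = -r0, rows - 1 - r1
    dc_lo, dc_hi = -c0, cols - 1 - c1
    if dr_lo > dr_hi or dc_lo > dc_hi:
        return None
    accepted: list[np.ndarray] = []
    n_acc = 0
    attempts = 0
    all_valid = study_mask.all()
    while n_acc < n_needed and attempts < max_attempts:
        batch = min(max(2 * (n_needed - n_acc), 64), max_attempts - attempts)
        dr = rng.integers(dr_lo, dr_hi + 1, size=batch)
        dc = rng.integers(dc_lo, dc_hi + 1, size=batch)
        attempts += batch
        if all_valid:
            ok = np.ones(batch, dtype=bool)
        else:
            # every translated cell must land on a study cell
            ok = study_mask[r[None, :] + dr[:, None], c[None, :] + dc[:, None]].all(axis=1)
        good = np.column_stack([dr[ok], dc[ok]])
        if len(good):
            accepted.append(good)
            n_acc += len(good)
    if n_acc < n_needed:
        return None
    return np.vstack(accepted)[:n_needed]


def relocate_footprint(
    footprint: np.ndarray, study_mask: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """One random rigid translation of the footprint inside the study area."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    off = _draw_offsets(footprint, study_mask, rng, 1)
    if off is None:
        raise RuntimeError("no valid placement found within the attempt cap")
    return footprint + off[0]


def effectiveness_test(
    pa: ProtectedArea,
    richness: RichnessMap,
    study_mask: np.ndarray | None = None,
    n_randomizations: int = DEFAULT_N_RANDOMIZATIONS,
    seed: int = 0,
) -> EffectivenessResult:
    """Randomization test of one PA against relocated copies of itself."""
    grid = richness.richness
    if study_mask is None:
        study_mask = np.ones(grid.shape, dtype=bool)
    observed = mean_richness_in(pa.footprint, richness)
    rng = _pa_rng(seed, pa.pa_id)
    offsets = _draw_offsets(pa.footprint, study_mask, rng, n_randomizations)
    if offsets is None:
        warnings.warn(f"{pa.pa_id}: relocation failed; PA untestable")
        return EffectivenessResult(
            pa.pa_id, pa.category, richness.scenario_id, observed,
            np.array([]), 0, float("nan"), False, untestable=True,
        )
    r = pa.footprint[:, 0][None, :] + offsets[:, 0][:, None]
    c = pa.footprint[:, 1][None, :] + offsets[:, 1][:, None]
    null_values = grid[r, c].mean(axis=1)
    n_greater = int(np.count_nonzero(observed > null_values))
    effective = n_greater >= ceil(0.95 * n_randomizations)
    p_value = (1 + int(np.count_nonzero(null_values >= observed))) / (1 + n_randomizations)
    return EffectivenessResult(
        pa.pa_id, pa.category, richness.scenario_id, observed,
        null_values, n_greater, p_value, effective,
    )


def run_effectiveness_tests(
    pas: ProtectedAreaSet,
    richness: RichnessMap,
    study_mask: np.ndarray | None = None,
    n_randomizations: int = DEFAULT_N_RANDOMIZATIONS,
    seed: int = 0,
) -> list[EffectivenessResult]:
    return [
        effectiveness_test(pa, richness, study_mask, n_randomizations, seed) for pa in pas
    ]


def summarize_effectiveness(results: list[EffectivenessResult]) -> dict:
    """Tally effective / non-effective / untestable PAs for one scenario."""
    if not results:
        raise ValueError("no results to summarize")
    n = len(results)
    eff = sum(r.effective for r in results)
    unt = sum(r.untestable for r in results)
    return {
        "scenario": results[0].scenario_id,
        "n_pas": n,
        "effective": eff,
        "non_effective": n - eff - unt,
        "untestable": unt,
        "pct_effective": 100.0 * eff / n,
    }
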