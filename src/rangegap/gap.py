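"""Gap analysis: per-taxon representation inside nested protected-area scenarios.

Each taxon's protection target scales with its range size following the
standard area-interpolated construction: taxa with ranges of 1,000 km² or
less should be fully (100%) covered by protected areas, taxa with
250,000 km² or more need at least 10% coverage, and targets in between are
interpolated linearly in log10(area):

    target(A) = 100 - 90 * (log10(A) - 3) / (log10(250000) - 3)

Representation achieved is the percentage of the taxon's range cells inside
the union of the scenario's PA footprints (overlaps counted once). Goal
attainment = 100 * achieved / target classifies the taxon:

    Protected      attainment >= 90
    Partial gap    20 < attainment < 90
    Gap            0 < attainment <= 20
    Not protected  attainment == 0, or the range itself is empty

Taxa lacking any suitable area in a scenario are always "Not protected".
PA scenarios are nested: SPA, SPA+SUA, SPA+SUA+IT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ProtectedAreaSet
from .postprocess import BinaryRange

__all__ = [
    "GapResult",
    "PA_SCENARIOS",
    "protection_target",
    "achieved_representation",
    "classify",
    "run_gap_scenarios",
    "gap_summary_table",
]

LOWER_AREA_KM2 = 1_000.0
UPPER_AREA_KM2 = 250_000.0

#: Nested PA scenarios, each a tuple of included categories.
PA_SCENARIOS: dict[str, tuple[str, ...]] = {
    "SPA": ("SPA",),
    "SPA+SUA": ("SPA", "SUA"),
    "SPA+SUA+IT": ("SPA", "SUA", "IT"),
}

CATEGORIES = ("Protected", "Partial gap", "Gap", "Not protected")


@dataclass
class GapResult:
    taxon_id: str
    climate_scenario: str
    pa_scenario: str
    range_area_km2: float
    target_pct: float
    achieved_pct: float
    goal_attainment_pct: float
    category: str
    range_empty: bool


def protection_target(area_km2: float) -> float:
    """Area-scaled protection target in percent (log-linear interpolation)."""
    if area_km2 < 0:
        raise ValueError("area must be non-negative")
    if area_km2 <= LOWER_AREA_KM2:
        return 100.0
    if area_km2 >= UPPER_AREA_KM2:
        return 10.0
    frac = (np.log10(area_km2) - np.log10(LOWER_AREA_KM2)) / (
        np.log10(UPPER_AREA_KM2) - np.log10(LOWER_AREA_KM2)
    )
    return 100.0 - 90.0 * frac


def achieved_representation(rng: BinaryRange, pa_union: np.ndarray) -> float:
    """Percent of the range's cells inside the PA union; 0 for an empty range."""
    if pa_union.shape != rng.cells.shape:
        raise ValueError("PA mask shape does not match range grid")
    n_range = rng.n_cells
    if n_range == 0:
        return 0.0
    return 100.0 * np.count_nonzero(rng.cells & pa_union) / n_range


def classify(goal_attainment_pct: float, range_empty: bool = False) -> str:
    """Protection category from goal attainment and range emptiness."""
    if goal_attainment_pct < 0:
        raise ValueError("attainment must be non-negative")
    if range_empty or goal_attainment_pct == 0:
        return "Not protected"
    if goal_attainment_pct >= 90:
        return "Protected"
    if goal_attainment_pct > 20:
        return "Partial gap"
    return "Gap"


def evaluate_taxon(
    rng: BinaryRange, pa_union: np.ndarray, pa_scenario: str
) -> GapResult:
    area = rng.area_km2
    target = protection_target(area)
    achieved = achieved_representation(rng, pa_union)
    attainment = 0.0 if rng.is_empty else 100.0 * achieved / target
    return GapResult(
        taxon_id=rng.taxon_id,
        climate_scenario=rng.scenario_id,
        pa_scenario=pa_scenario,
        range_area_km2=area,
        target_pct=target,
        achieved_pct=achieved,
        goal_attainment_pct=attainment,
        category=classify(attainment, rng.is_empty),
        range_empty=rng.is_empty,
    )


def run_gap_scenarios(
    ranges: dict[str, list[BinaryRange]],
    pas: ProtectedAreaSet,
    grid_shape: tuple[int, int],
    pa_scenarios: dict[str, tuple[str, ...]] | None = None,
) -> list[GapResult]:
    """Gap analysis over every climate scenario x nested PA scenario x taxon.

    ``ranges`` maps climate-scenario id to the per-taxon binary ranges of
    that scenario.
    """
    if not ranges or not any(ranges.values()):
        raise ValueError("need at least one taxon range")
    if pa_scenarios is None:
        pa_scenarios = PA_SCENARIOS
    unions = {
        name: pas.subset(cats).union_mask(grid_shape) for name, cats in pa_scenarios.items()
    }
    results: list[GapResult] = []
    for clim, taxa_ranges in ranges.items():
        for pa_name, mask in unions.items():
            for rng in taxa_ranges:
                results.append(evaluate_taxon(rng, mask, pa_name))
    return results


def gap_results_frame(results: list[GapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": r.taxon_id,
            "climate_scenario": r.climate_scenario,
            "pa_scenario": r.pa_scenario,
            "area_km2": r.range_area_km2,
            "target_pct": r.target_pct,
            "achieved_pct": r.achieved_pct,
            "attainment_pct": r.goal_attainment_pct,
            "category": r.category,
            "range_empty": r.range_empty,
        }
        for r in results
    )


def gap_summary_table(results: list[GapResult]) -> pd.DataFrame:
    """Category x (climate scenario, PA scenario) count table; columns sum to n taxa."""
    df = gap_results_frame(results)
    pivot = (
        df.pivot_table(
            index="category",
            columns=["climate_scenario", "pa_scenario"],
            values="taxon_id",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(list(CATEGORIES))
        .fillna(0)
        .astype(int)
    )
    pivot.loc["Total"] = pivot.sum(axis=0)
    return pivot
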