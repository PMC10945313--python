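"""End-to-end pipeline: synthetic study -> axes -> SDMs -> ranges -> PA assessment.

The pipeline reproduces the full assessment workflow on a synthetic
landscape: generate (or load) climate for the present and two future
scenarios, reduce variables to principal axes fit on the present, model
each taxon inside its endemism-based calibration region, ensemble the
above-average algorithms, binarize at the Jaccard-optimal threshold,
apply the forest land-cover mask, stack ranges into richness maps, test
every protected area against its relocation null model, and run the gap
analysis over the three nested PA scenarios.

Every stage writes its outputs as files under the output directory; no
stage mutates another stage's outputs. All randomness derives from the
single configured seed through stable per-stage substreams, so a rerun is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envreduce, gap, io, nullmodel, postprocess, sdm, synth
from .grids import GridGeometry

logger = logging.getLogger("rangegap")

SCENARIOS = ("present", "future-optimistic", "future-pessimistic")


def derive_seed(master: int, *keys) -> int:
    """Stable sub-seed for a named pipeline stage (always < 2^31)."""
    tag = ":".join(str(k) for k in (master, *keys))
    return zlib.crc32(tag.encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """All knobs of a synthetic study; loadable from a YAML file."""

    seed: int = 1
    grid_shape: tuple[int, int] = (50, 50)
    n_vars: int = 6
    autocorr_scale: float = 5.0
    cell_area_km2: float = 25.0
    # future scenarios: per-scenario uniform shift applied to the first half
    # of the variables (the "temperature-like" block), plus autocorrelated noise
    shift_optimistic: float = 1.0
    shift_pessimistic: float = 2.0
    future_noise_sd: float = 0.2
    # virtual taxa
    n_taxa: int = 12
    occ_min: int = 8
    occ_max: int = 518
    range_cut: float = 0.5
    niche_breadth: tuple[float, float] = (0.6, 1.4)
    endemism_margin: int = 5
    n_floodplain_taxa: int = 1
    # protected areas
    n_pas: int = 60
    pa_size_range: tuple[int, int] = (2, 8)
    pa_category_weights: dict = field(
        default_factory=lambda: {"SPA": 1.0, "SUA": 1.0, "IT": 1.0}
    )
    # land cover
    forest_fraction: float = 0.8
    landcover_autocorr: float = 5.0
    # analysis settings
    variance_target: float = 0.95
    pa_ratio: float = 1.0
    block_size: int | None = None
    k: int = 5
    ensemble_metric: str = "jaccard_max"
    n_randomizations: int = 999
    out_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.grid_shape = tuple(cfg.grid_shape)
        cfg.pa_size_range = tuple(cfg.pa_size_range)
        cfg.niche_breadth = tuple(cfg.niche_breadth)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d


def _future_shift(cfg: PipelineConfig, delta: float) -> np.ndarray:
    shift = np.zeros(cfg.n_vars)
    shift[: (cfg.n_vars + 1) // 2] = delta
    return shift


def build_study(cfg: PipelineConfig) -> dict:
    """Generate the synthetic study inputs (climate, taxa, occurrences, PAs, land cover)."""
    seed = cfg.seed
    present = synth.generate_landscape(
        derive_seed(seed, "landscape"),
        cfg.grid_shape,
        cfg.n_vars,
        cfg.autocorr_scale,
        cell_area=cfg.cell_area_km2,
    )
    stacks = {"present": present}
    for name, delta in (
        ("future-optimistic", cfg.shift_optimistic),
        ("future-pessimistic", cfg.shift_pessimistic),
    ):
        stacks[name] = synth.generate_future(
            present,
            _future_shift(cfg, delta),
            noise_sd=cfg.future_noise_sd,
            seed=derive_seed(seed, "future", name),
            scenario_id=name,
            autocorr_scale=cfg.autocorr_scale,
        )

    rng = np.random.default_rng(derive_seed(seed, "taxa"))
    valid_cells = np.argwhere(present.valid_mask)
    species, occurrences = [], []
    for i in range(cfg.n_taxa):
        taxon = f"taxon_{i + 1:02d}"
        # optimum at a real cell's climate so the range is never empty
        anchor = valid_cells[rng.integers(len(valid_cells))]
        niche = {}
        for v, name in enumerate(present.var_names):
            opt = present.layers[v, anchor[0], anchor[1]]
            breadth = rng.uniform(*cfg.niche_breadth)
            niche[name] = (float(opt), float(breadth))
        sp = synth.generate_virtual_species(
            present, niche, cfg.range_cut, taxon_id=taxon, endemism_margin=cfg.endemism_margin
        )
        species.append(sp)
        n_cells = int(sp.true_range.sum())
        n_occ = int(
            np.round(np.exp(rng.uniform(np.log(cfg.occ_min), np.log(cfg.occ_max))))
        )
        n_occ = max(3, min(n_occ, n_cells))
        occurrences.append(
            synth.sample_occurrences(sp, n_occ, derive_seed(seed, "occ", taxon))
        )

    pas = synth.generate_protected_areas(
        cfg.grid_shape,
        cfg.n_pas,
        cfg.pa_size_range,
        cfg.pa_category_weights,
        derive_seed(seed, "pas"),
    )
    landcover = synth.generate_landcover(
        cfg.grid_shape, cfg.forest_fraction, cfg.landcover_autocorr, derive_seed(seed, "lc")
    )
    floodplain = {sp.taxon_id for sp in species[: cfg.n_floodplain_taxa]}
    return {
        "stacks": stacks,
        "species": species,
        "occurrences": occurrences,
        "pas": pas,
        "landcover": landcover,
        "floodplain_taxa": floodplain,
    }


def model_taxon(
    cfg: PipelineConfig,
    occ,
    calibration_mask: np.ndarray,
    score_stacks: dict[str, envreduce.ScoreStack],
) -> tuple[dict[str, sdm.EnsembleResult], float, pd.DataFrame]:
    """Fit, evaluate and ensemble one taxon; returns per-scenario ensembles,
    the present-data Jaccard-optimal threshold, and the evaluation report."""
    registry = sdm.default_registry()
    present_scores = score_stacks["present"]
    ts = sdm.build_training_set(
        occ, present_scores, calibration_mask, cfg.pa_ratio, derive_seed(cfg.seed, "bg", occ.taxon_id)
    )
    scheme = sdm.partition(
        ts, occ.n_unique, derive_seed(cfg.seed, "fold", occ.taxon_id), cfg.block_size, cfg.k
    )
    results = sdm.fit_estimators(
        ts, scheme, registry, present_scores, metric=cfg.ensemble_metric
    )
    ensembles = {"present": sdm.ensemble(results, occ.taxon_id, "present")}
    retained = set(ensembles["present"].retained_algorithms)
    for scen, scores in score_stacks.items():
        if scen == "present":
            continue
        future_results = sdm.predict_scenario(ts, results, registry, scores)
        ens = sdm.ensemble(future_results, occ.taxon_id, scen)
        assert set(ens.retained_algorithms) == retained  # metrics carry over
        ensembles[scen] = ens
    threshold = postprocess.select_threshold(
        ensembles["present"].suitability, ts.presence_cells, ts.absence_cells
    )
    report = pd.DataFrame(
        {
            "taxon_id": occ.taxon_id,
            "algorithm": r.algorithm_id,
            "fold": m["fold"],
            "auc": m["auc"],
            "jaccard_max": m["jaccard_max"],
            "retained": r.algorithm_id in retained,
            "partition": scheme.method,
        }
        for r in results
        for m in r.fold_metrics
    )
    return ensembles, threshold, report


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run every stage and write all tables/rasters; returns the output directory."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = build_study(cfg)
    stacks = study["stacks"]
    present = stacks["present"]
    geometry = present.geometry

    logger.info("fitting principal axes (variance target %.2f)", cfg.variance_target)
    model = envreduce.fit_axes(present, cfg.variance_target)
    model.to_json(out / "axis_model.json")
    score_stacks = {name: envreduce.project(stack, model) for name, stack in stacks.items()}
    logger.info("kept %d of %d axes", model.n_axes_kept, present.n_vars)

    reports, ranges, area_rows = [], {s: [] for s in stacks}, []
    for sp, occ in zip(study["species"], study["occurrences"]):
        logger.info("modelling %s (%d occurrences)", occ.taxon_id, occ.n_unique)
        ensembles, threshold, report = model_taxon(cfg, occ, sp.endemism_region, score_stacks)
        reports.append(report)
        present_range = postprocess.binarize(
            ensembles["present"].suitability,
            threshold,
            occ.taxon_id,
            "present",
            present.valid_mask,
            cfg.cell_area_km2,
        )
        present_range = postprocess.apply_forest_mask(present_range, study["landcover"])
        ranges["present"].append(present_range)
        for scen in stacks:
            if scen == "present":
                continue
            fut = postprocess.binarize(
                ensembles[scen].suitability,
                threshold,
                occ.taxon_id,
                scen,
                present.valid_mask,
                cfg.cell_area_km2,
            )
            fut = postprocess.apply_forest_mask(fut, study["landcover"])
            if occ.taxon_id in study["floodplain_taxa"]:
                fut = postprocess.restrict_future_to_present(fut, present_range)
            ranges[scen].append(fut)
            if present_range.n_cells > 0:
                area_rows.append(postprocess.area_change(present_range, fut))

    pd.concat(reports, ignore_index=True).to_csv(out / "evaluation_report.csv", index=False)
    pd.DataFrame(area_rows).to_csv(out / "area_change.csv", index=False)

    richness = {}
    for scen, rngs in ranges.items():
        rm = postprocess.stack_richness(rngs, grid_shape=present.grid_shape)
        rm.scenario_id = rm.scenario_id or scen
        richness[scen] = rm
        io.write_richness(rm, out / f"richness_{scen}.asc", geometry)

    eff_rows, summaries = [], []
    for scen, rm in richness.items():
        logger.info("PA null model, scenario %s (%d PAs)", scen, len(study["pas"]))
        results = nullmodel.run_effectiveness_tests(
            study["pas"], rm, present.valid_mask, cfg.n_randomizations, derive_seed(cfg.seed, "null")
        )
        summaries.append(nullmodel.summarize_effectiveness(results))
        for r in results:
            eff_rows.append(
                {
                    "pa_id": r.pa_id,
                    "category": r.category,
                    "scenario": scen,
                    "observed": r.observed_mean_richness,
                    "null_mean": float(r.null_values.mean()) if len(r.null_values) else np.nan,
                    "null_sd": float(r.null_values.std()) if len(r.null_values) else np.nan,
                    "n_observed_greater": r.n_observed_greater,
                    "p_value": r.p_value,
                    "effective": r.effective,
                    "untestable": r.untestable,
                }
            )
    pd.DataFrame(eff_rows).to_csv(out / "pa_effectiveness.csv", index=False)
    pd.DataFrame(summaries).to_csv(out / "pa_effectiveness_summary.csv", index=False)

    gap_results = gap.run_gap_scenarios(ranges, study["pas"], present.grid_shape)
    gap.gap_results_frame(gap_results).to_csv(out / "gap_results.csv", index=False)
    gap.gap_summary_table(gap_results).to_csv(out / "gap_summary.csv")

    io.write_protected_areas_geojson(study["pas"], out / "protected_areas.geojson", geometry)
    io.write_occurrences(study["occurrences"], out / "occurrences.csv", geometry)
    io.write_landcover(study["landcover"], out / "landcover.asc")

    import rangegap

    provenance = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "version": rangegap.__version__,
        "n_axes_kept": model.n_axes_kept,
        "scenarios": list(stacks),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
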