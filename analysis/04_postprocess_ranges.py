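"""Binarize suitability, apply the forest mask, compute area change and richness.

Reads the suitability rasters and thresholds from the SDM stage, cuts each
map at its taxon's present-data Jaccard threshold, keeps only forest
cells, clips floodplain taxa's future ranges to their present ranges, and
stacks per-scenario ranges into richness maps.
"""

import numpy as np
import pandas as pd

from common import RESULTS, study_config
from rangegap import io, postprocess
from rangegap.pipeline import SCENARIOS, build_study

cfg = study_config()
study = build_study(cfg)  # deterministic regeneration for land cover / floodplain list
geometry = study["stacks"]["present"].geometry
valid = study["stacks"]["present"].valid_mask
landcover = study["landcover"]

thresholds = pd.read_csv(RESULTS / "thresholds.csv").set_index("taxon_id")
ranges = {s: [] for s in SCENARIOS}
area_rows = []
for taxon, row in thresholds.iterrows():
    per_scen = {}
    for scen in SCENARIOS:
        suit, _, _ = io.read_ascii_grid(RESULTS / "suitability" / f"{taxon}_{scen}.asc")
        br = postprocess.binarize(
            suit, row["threshold"], taxon, scen, valid, cfg.cell_area_km2
        )
        br = postprocess.apply_forest_mask(br, landcover)
        if scen != "present" and row["floodplain"]:
            br = postprocess.restrict_future_to_present(br, per_scen["present"])
        per_scen[scen] = br
        ranges[scen].append(br)
    if per_scen["present"].n_cells > 0:
        for scen in SCENARIOS[1:]:
            area_rows.append(postprocess.area_change(per_scen["present"], per_scen[scen]))

areas = pd.DataFrame(area_rows)
areas.to_csv(RESULTS / "area_change.csv", index=False)
for scen, rngs in ranges.items():
    rm = postprocess.stack_richness(rngs, grid_shape=valid.shape)
    rm.scenario_id = rm.scenario_id or scen
    io.write_richness(rm, RESULTS / f"richness_{scen}.asc", geometry)
    print(f"{scen}: max cell richness {rm.richness.max()}, "
          f"mean {rm.richness.mean():.2f} taxa/cell")

for scen, grp in areas.groupby("scenario"):
    big_loss = (grp["pct_change"] < -80).sum()
    total = grp["total_loss"].sum()
    print(f"{scen}: {big_loss}/{len(grp)} taxa lose >80% of suitable area; "
          f"{total} lose effectively all of it (>99%)")
print(f"tables and richness rasters in {RESULTS}")
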