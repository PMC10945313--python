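"""Generate the synthetic study system and write its inputs to disk.

Produces one present and two future climate scenarios (a moderate and a
strong warming shift on the temperature-like variables), 20 virtual taxa
with known niches, occurrence samples spanning realistic record counts,
150 protected areas in three categories, and a clumped land-cover grid.
"""

import numpy as np

from common import RESULTS, study_config
from rangegap import io
from rangegap.pipeline import build_study

cfg = study_config()
study = build_study(cfg)
outdir = RESULTS / "inputs"
outdir.mkdir(parents=True, exist_ok=True)

geometry = study["stacks"]["present"].geometry
for name, stack in study["stacks"].items():
    io.write_climate_stack(stack, outdir / f"climate_{name}")
io.write_occurrences(study["occurrences"], outdir / "occurrences.csv", geometry)
io.write_protected_areas_geojson(study["pas"], outdir / "protected_areas.geojson", geometry)
io.write_pa_mask(study["pas"], outdir / "pa_mask.asc", geometry)
io.write_landcover(study["landcover"], outdir / "landcover.asc")

n_occ = [o.n_unique for o in study["occurrences"]]
range_sz = [int(sp.true_range.sum()) for sp in study["species"]]
cats = {c: sum(a.category == c for a in study["pas"]) for c in ("SPA", "SUA", "IT")}
print(f"wrote study inputs to {outdir}")
print(f"taxa: {cfg.n_taxa}; occurrences per taxon {min(n_occ)}-{max(n_occ)} "
      f"(median {int(np.median(n_occ))}); true-range sizes {min(range_sz)}-{max(range_sz)} cells")
print(f"protected areas: {len(study['pas'])} ({cats})")
print(f"forest share: {study['landcover'].forest_mask.mean():.2f}")
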