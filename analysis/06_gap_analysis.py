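"""Gap analysis of per-taxon representation in nested PA scenarios.

For each climate scenario and each nested PA scenario (SPA, SPA+SUA,
SPA+SUA+IT), compares the protected share of every taxon's range with its
area-scaled target and classifies the taxon as Protected / Partial gap /
Gap / Not protected. Prints the category-count summary table.
"""

import pandas as pd

from common import RESULTS, study_config
from rangegap import gap, io, postprocess
from rangegap.pipeline import SCENARIOS, build_study

cfg = study_config()
study = build_study(cfg)
valid = study["stacks"]["present"].valid_mask

thresholds = pd.read_csv(RESULTS / "thresholds.csv").set_index("taxon_id")
landcover = study["landcover"]
ranges = {s: [] for s in SCENARIOS}
for taxon, row in thresholds.iterrows():
    per_scen = {}
    for scen in SCENARIOS:
        suit, _, _ = io.read_ascii_grid(RESULTS / "suitability" / f"{taxon}_{scen}.asc")
        br = postprocess.binarize(suit, row["threshold"], taxon, scen, valid, cfg.cell_area_km2)
        br = postprocess.apply_forest_mask(br, landcover)
        if scen != "present" and row["floodplain"]:
            br = postprocess.restrict_future_to_present(br, per_scen["present"])
        per_scen[scen] = br
        ranges[scen].append(br)

results = gap.run_gap_scenarios(ranges, study["pas"], valid.shape)
gap.gap_results_frame(results).to_csv(RESULTS / "gap_results.csv", index=False)
table = gap.gap_summary_table(results)
table.to_csv(RESULTS / "gap_summary.csv")

print("taxon counts per protection category (columns: climate x PA scenario):")
print(table.to_string())
print(f"gap tables in {RESULTS}")
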