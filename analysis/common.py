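"""Shared configuration for the numbered analysis scripts.

The study landscape is larger than the bundled demo — an 80x80 grid (~160,000
km² at 25 km² cells) with 20 virtual taxa and 150 protected areas — big
enough for spatial structure to matter while keeping every script under a
minute on one CPU. Stages recompute deterministically from the same seed, so
each script is independently runnable.
"""

from pathlib import Path

from rangegap.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"


def study_config() -> PipelineConfig:
    return PipelineConfig(
        seed=1,
        grid_shape=(80, 80),
        n_vars=6,
        n_taxa=20,
        n_pas=150,
        n_floodplain_taxa=2,
        n_randomizations=999,
        forest_fraction=0.8,
        out_dir=str(RESULTS),
    )
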