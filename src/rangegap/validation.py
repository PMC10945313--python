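"""Validation experiments for the pipeline's statistical machinery.

These are the package's own checks that its primitives behave as designed,
run on synthetic data where the truth is known:

* oracle agreement of the threshold selector and the rank AUC against
  brute-force enumeration;
* type-I-error calibration of the protected-area relocation null model on a
  richness field generated independently of PA placement (the fraction of
  PAs flagged effective should sit near the nominal 5%);
* parameter recovery — how well the full modelling chain (axes -> ensemble
  SDM -> Jaccard threshold) reconstructs a virtual species' true range from
  a limited occurrence sample.

Both the test suite and ``scripts/acceptance.py`` drive these functions.
"""

from __future__ import annotations

import numpy as np

from . import envreduce, nullmodel, postprocess, sdm, synth
from .pipeline import derive_seed
from .postprocess import RichnessMap
from .synth import _smooth_field


def threshold_oracle_agreement(n_instances: int = 100, seed: int = 0, max_n: int = 200) -> dict:
    """Compare the Jaccard-threshold selector with exhaustive search over [0, 1].

    Returns the worst absolute difference in achieved Jaccard between the
    selected threshold and a dense 401-point sweep, over random instances.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_done = 0
    while n_done < n_instances:
        n = int(rng.integers(4, max_n + 1))
        suit = rng.integers(0, 25, size=(1, n)) / 25.0
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        pres = np.column_stack([np.zeros(labels.sum(), int), np.nonzero(labels)[0]])
        absn = np.column_stack([np.zeros((~labels).sum(), int), np.nonzero(~labels)[0]])
        t = postprocess.select_threshold(suit, pres, absn)
        ours = sdm.jaccard(suit[0] >= t, labels)
        oracle = max(sdm.jaccard(suit[0] >= x, labels) for x in np.linspace(0, 1, 401))
        worst = max(worst, abs(ours - oracle))
        n_done += 1
    return {"n_instances": n_done, "max_abs_difference": worst}


def auc_oracle_agreement(n_instances: int = 100, seed: int = 0, max_side: int = 50) -> dict:
    """Compare the rank AUC with brute-force pairwise concordance (ties = 1/2)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        pos = rng.integers(0, 10, size=int(rng.integers(1, max_side + 1))) / 10.0
        neg = rng.integers(0, 10, size=int(rng.integers(1, max_side + 1))) / 10.0
        brute = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg) / (len(pos) * len(neg))
        worst = max(worst, abs(sdm.auc(pos, neg) - brute))
    return {"n_instances": n_instances, "max_abs_difference": worst}


def null_model_calibration(
    n_pas: int = 200,
    n_randomizations: int = 999,
    grid_shape: tuple[int, int] = (100, 100),
    max_richness: int = 12,
    autocorr_scale: float = 5.0,
    seed: int = 0,
) -> dict:
    """Type-I error of the effectiveness test under a richness-independent PA layout.

    The richness field is an autocorrelated surface scaled to integer counts
    and the PAs are placed uniformly at random, so no PA is genuinely
    "effective"; under the strict-greater >= 95% counting rule roughly 5% of
    PAs should be flagged by chance.
    """
    rng = np.random.default_rng(derive_seed(seed, "calibration-field"))
    field = _smooth_field(rng, grid_shape, autocorr_scale)
    lo, hi = field.min(), field.max()
    rich = np.round(max_richness * (field - lo) / (hi - lo)).astype(int)
    rm = RichnessMap("calibration", rich, [])
    pas = synth.generate_protected_areas(
        grid_shape, n_pas, (2, 8), seed=derive_seed(seed, "calibration-pas")
    )
    results = nullmodel.run_effectiveness_tests(
        pas, rm, None, n_randomizations, derive_seed(seed, "calibration-null")
    )
    frac = float(np.mean([r.effective for r in results]))
    return {"n_pas": len(pas), "n_randomizations": n_randomizations, "fraction_effective": frac}


def recover_one_species(seed: int, grid_shape=(50, 50), n_vars=6, occ_range=(30, 100)) -> dict:
    """Full modelling chain on one virtual species; Jaccard vs the true range."""
    stack = synth.generate_landscape(derive_seed(seed, "land"), grid_shape, n_vars, 5.0)
    model = envreduce.fit_axes(stack)
    scores = envreduce.project(stack, model)
    rng = np.random.default_rng(derive_seed(seed, "niche"))
    cells = np.argwhere(stack.valid_mask)
    anchor = cells[rng.integers(len(cells))]
    niche = {
        v: (float(stack.layers[i, anchor[0], anchor[1]]), float(rng.uniform(0.6, 1.4)))
        for i, v in enumerate(stack.var_names)
    }
    sp = synth.generate_virtual_species(stack, niche, 0.5, taxon_id=f"virtual_{seed}")
    n = int(rng.integers(occ_range[0], occ_range[1] + 1))
    n = min(n, int(sp.true_range.sum()))
    occ = synth.sample_occurrences(sp, n, derive_seed(seed, "occ"))
    ts = sdm.build_training_set(occ, scores, sp.endemism_region, 1.0, derive_seed(seed, "bg"))
    scheme = sdm.partition(ts, occ.n_unique, derive_seed(seed, "fold"))
    results = sdm.fit_estimators(ts, scheme, scores=scores)
    ens = sdm.ensemble(results, occ.taxon_id, "present")
    t = postprocess.select_threshold(ens.suitability, ts.presence_cells, ts.absence_cells)
    br = postprocess.binarize(ens.suitability, t, valid_mask=stack.valid_mask)
    return {
        "seed": seed,
        "n_occurrences": n,
        "true_range_cells": int(sp.true_range.sum()),
        "jaccard": sdm.jaccard(br.cells, sp.true_range),
    }


def parameter_recovery(n_species: int = 10, seed: int = 0, **kwargs) -> dict:
    """Recovery experiment over several virtual species; reports the median Jaccard."""
    records = [
        recover_one_species(derive_seed(seed, "recovery", i), **kwargs)
        for i in range(1, n_species + 1)
    ]
    return {
        "n_species": n_species,
        "median_jaccard": float(np.median([r["jaccard"] for r in records])),
        "per_species": records,
    }
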