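"""Per-taxon presence/pseudo-absence modelling, evaluation and ensembling.

Each taxon is modelled inside its calibration region (the endemism region
containing its occurrences). Pseudo-absences are drawn uniformly from
calibration cells without a presence, at a configurable presence:absence
ratio (default 1:1). Evaluation uses geographically structured two-fold
"checkerboard" cross-validation for taxa with >= 15 unique occurrences and
random k-fold otherwise. Two metrics are computed per evaluation fold: the
rank-based AUC and the maximum Jaccard similarity over candidate
thresholds. The final map is the cell-wise mean of the algorithms whose
mean metric is at or above the across-algorithm average ("ensemble of
above-average models").

The estimator registry is pluggable: anything exposing ``fit(X, y)`` and
``score_samples(X) -> 1-D array`` (higher = more suitable) can participate.
Two concrete estimators ship: a regularized logistic model and a Gaussian
environmental-envelope scorer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .envreduce import ScoreStack
from .grids import OccurrenceSet, as_cell_array

__all__ = [
    "TrainingSet",
    "PartitionScheme",
    "EstimatorResult",
    "EnsembleResult",
    "LogisticEstimator",
    "GaussianEnvelopeEstimator",
    "default_registry",
    "build_training_set",
    "partition",
    "auc",
    "jaccard",
    "jaccard_max",
    "evaluate_estimator",
    "fit_estimators",
    "ensemble",
]

CHECKERBOARD_MIN_N = 15  # unique occurrences at or above which spatial blocking is used
DEFAULT_K = 5


# ---------------------------------------------------------------------------
# containers


@dataclass
class TrainingSet:
    taxon_id: str
    presence_cells: np.ndarray  # (n_p, 2)
    absence_cells: np.ndarray  # (n_a, 2)
    features: np.ndarray  # (n_p + n_a, n_axes), presences first
    labels: np.ndarray  # bool
    calibration_mask: np.ndarray

    @property
    def cells(self) -> np.ndarray:
        return np.vstack([self.presence_cells, self.absence_cells])


@dataclass
class PartitionScheme:
    method: str  # "checkerboard" | "kfold"
    fold_of_record: np.ndarray  # int fold id per training record
    block_size: int | None = None
    k: int | None = None

    @property
    def n_folds(self) -> int:
        return int(self.fold_of_record.max()) + 1


@dataclass
class EstimatorResult:
    algorithm_id: str
    fold_metrics: list[dict]  # per-fold {"fold", "auc", "jaccard_max"}
    mean_metric: float
    suitability: np.ndarray  # (rows, cols) in [0,1]; NaN outside calibration
    #: (lo, hi) of the raw present-scenario scores; reused to scale other
    #: scenarios so absolute suitability changes stay visible
    scale_bounds: tuple[float, float] | None = None


@dataclass
class EnsembleResult:
    taxon_id: str
    scenario_id: str
    retained_algorithms: list[str]
    suitability: np.ndarray
    member_results: list[EstimatorResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# estimators


class LogisticEstimator:
    """L2-regularized logistic regression on the axis scores (GLM family)."""

    algorithm_id = "logistic"

    def __init__(self, C: float = 1.0):
        self.C = C
        self._model = None

    def fit(self, X, y):
        self._model = LogisticRegression(C=self.C, max_iter=1000)
        self._model.fit(X, np.asarray(y, dtype=int))
        return self

    def score_samples(self, X):
        return self._model.predict_proba(X)[:, 1]


class GaussianEnvelopeEstimator:
    """Gaussian environmental envelope fitted to presences only.

    Scores are the Mahalanobis-distance density exp(-d²/2) around the
    presence centroid in axis space (regularized covariance), a profile
    (envelope/climatic-distance) family model: pseudo-absences play no role
    in the fit, only in evaluation.
    """

    algorithm_id = "gauss_envelope"

    def __init__(self, reg: float = 1e-6):
        self.reg = reg
        self._mean = None
        self._prec = None

    def fit(self, X, y):
        P = np.asarray(X)[np.asarray(y, dtype=bool)]
        if len(P) == 0:
            raise ValueError("no presences to fit the envelope")
        self._mean = P.mean(axis=0)
        cov = np.cov(P.T) if len(P) > 1 else np.eye(P.shape[1])
        cov = np.atleast_2d(cov) + self.reg * np.eye(P.shape[1])
        # inflate degenerate axes so the inverse stays tame
        d = np.diag(cov).copy()
        d[d < 1e-3] = 1e-3
        cov[np.diag_indices_from(cov)] = d
        self._prec = np.linalg.inv(cov)
        return self

    def score_samples(self, X):
        D = np.asarray(X) - self._mean
        d2 = np.einsum("ij,jk,ik->i", D, self._prec, D)
        return np.exp(-0.5 * d2)


def default_registry() -> list:
    return [LogisticEstimator(), GaussianEnvelopeEstimator()]


# ---------------------------------------------------------------------------
# training data and partitioning


def build_training_set(
    occ: OccurrenceSet,
    scores: ScoreStack,
    calibration_mask: np.ndarray,
    pa_ratio: float = 1.0,
    seed: int = 0,
) -> TrainingSet:
    """Presences plus uniform-background pseudo-absences inside the calibration area."""
    if pa_ratio <= 0:
        raise ValueError("pa_ratio must be > 0")
    pres = as_cell_array(occ.cells)
    inside = calibration_mask[pres[:, 0], pres[:, 1]]
    if not inside.all():
        raise ValueError(
            f"{occ.taxon_id}: {np.count_nonzero(~inside)} presences fall outside "
            "the calibration area"
        )
    cand = calibration_mask & scores.valid_mask
    cand[pres[:, 0], pres[:, 1]] = False
    cand_cells = np.argwhere(cand)
    n_abs = int(round(pa_ratio * len(pres)))
    if len(cand_cells) < n_abs:
        raise ValueError(
            f"{occ.taxon_id}: need {n_abs} pseudo-absence cells but only "
            f"{len(cand_cells)} candidates are available"
        )
    rng = np.random.default_rng(seed)
    absent = cand_cells[rng.choice(len(cand_cells), size=n_abs, replace=False)]
    cells = np.vstack([pres, absent])
    X = scores.features_at(cells)
    y = np.zeros(len(cells), dtype=bool)
    y[: len(pres)] = True
    return TrainingSet(occ.taxon_id, pres, absent, X, y, calibration_mask)


def _checkerboard_folds(cells: np.ndarray, block: int) -> np.ndarray:
    return ((cells[:, 0] // block) + (cells[:, 1] // block)) % 2


def checkerboard_fold(row: int, col: int, block_size: int) -> int:
    """Fold id of a cell under the two-fold spatial checkerboard (pure function)."""
    return int(((row // block_size) + (col // block_size)) % 2)


def partition(
    ts: TrainingSet,
    n_unique: int | None = None,
    seed: int = 0,
    block_size: int | None = None,
    k: int = DEFAULT_K,
) -> PartitionScheme:
    """Assign training records to evaluation folds.

    Taxa with >= 15 unique occurrences get the spatial checkerboard (two
    folds by block parity); sparser taxa get random balanced k-fold with
    k capped at the occurrence count. A checkerboard leaving one fold with
    no presences is retried at half the block size, falling back to k-fold
    at block size 1.
    """
    if n_unique is None:
        n_unique = len(ts.presence_cells)
    if n_unique < 3:
        raise ValueError("need at least 3 unique occurrences to partition")

    if n_unique >= CHECKERBOARD_MIN_N:
        if block_size is None:
            cols = np.argwhere(ts.calibration_mask)[:, 1]
            width = int(cols.max() - cols.min() + 1) if len(cols) else 10
            block_size = max(width // 10, 2)
        block = block_size
        while block >= 1:
            folds = _checkerboard_folds(ts.cells, block)
            pres_folds = folds[ts.labels]
            if set(pres_folds.tolist()) == {0, 1}:
                return PartitionScheme("checkerboard", folds, block_size=block)
            if block == 1:
                break
            block = max(block // 2, 1)
        warnings.warn(
            f"{ts.taxon_id}: checkerboard left a fold without presences even at "
            "block size 1; falling back to k-fold"
        )

    k_eff = min(k, n_unique)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(ts.labels), dtype=int)
    for cls in (True, False):  # deal presences and absences round-robin separately
        idx = np.nonzero(ts.labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        folds[idx] = np.arange(len(idx)) % k_eff
    return PartitionScheme("kfold", folds, k=k_eff)


# ---------------------------------------------------------------------------
# metrics


def auc(pos_scores, neg_scores) -> float:
    """Rank-based AUC: probability a random positive outscores a random negative.

    Ties count one half (Mann-Whitney formulation).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def jaccard(predicted, observed) -> float:
    """Jaccard similarity TP/(TP+FP+FN) between predicted and observed presence sets."""
    p = np.asarray(predicted, dtype=bool)
    o = np.asarray(observed, dtype=bool)
    tp = np.count_nonzero(p & o)
    union = np.count_nonzero(p | o)
    return 1.0 if union == 0 else tp / union


def jaccard_max(scores, labels) -> tuple[float, float]:
    """Best Jaccard over candidate thresholds (the unique score values).

    Returns ``(best_jaccard, best_threshold)``; ties in Jaccard are broken
    by the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    best_j, best_t = -1.0, None
    for t in np.unique(scores):
        j = jaccard(scores >= t, labels)
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_j, best_t


def evaluate_estimator(scores, labels) -> dict:
    """AUC and threshold-maximized Jaccard on one evaluation fold."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("evaluation fold needs at least one presence and one absence")
    scores = np.asarray(scores, dtype=float)
    jm, _ = jaccard_max(scores, labels)
    return {"auc": auc(scores[labels], scores[~labels]), "jaccard_max": jm}


# ---------------------------------------------------------------------------
# fitting and ensembling


def _minmax(x: np.ndarray, bounds: tuple[float, float] | None = None) -> np.ndarray:
    """Scale to [0, 1]; with explicit bounds, values outside are clipped."""
    lo, hi = bounds if bounds is not None else (np.nanmin(x), np.nanmax(x))
    if hi == lo:
        return np.where(np.isnan(x), np.nan, 0.5)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def fit_estimators(
    ts: TrainingSet,
    scheme: PartitionScheme,
    registry: list | None = None,
    scores: ScoreStack | None = None,
    metric: str = "jaccard_max",
) -> list[EstimatorResult]:
    """Cross-validate each registered algorithm, then refit on all records.

    For each algorithm every fold is held out once for evaluation (both
    directions for the two-fold checkerboard). ``mean_metric`` averages the
    chosen metric over evaluation folds. The refit model predicts a
    suitability surface over the calibration area, min-max scaled to [0, 1]
    so algorithms with different output scales average sensibly.

    ``scores`` must be supplied to produce suitability maps; without it only
    metrics are computed.
    """
    if registry is None:
        registry = default_registry()
    if not registry:
        raise ValueError("estimator registry is empty")
    folds = scheme.fold_of_record
    results: list[EstimatorResult] = []
    for est in registry:
        fold_metrics = []
        try:
            for f in range(scheme.n_folds):
                test = folds == f
                train = ~test
                y_tr, y_te = ts.labels[train], ts.labels[test]
                if y_tr.all() or not y_tr.any() or y_te.all() or not y_te.any():
                    warnings.warn(
                        f"{ts.taxon_id}/{est.algorithm_id}: fold {f} lacks both "
                        "classes on one side; skipped"
                    )
                    continue
                est.fit(ts.features[train], y_tr)
                fm = evaluate_estimator(est.score_samples(ts.features[test]), y_te)
                fm["fold"] = f
                fold_metrics.append(fm)
            if not fold_metrics:
                warnings.warn(f"{ts.taxon_id}/{est.algorithm_id}: no usable folds; excluded")
                continue
            est.fit(ts.features, ts.labels)  # refit on everything
        except Exception as exc:  # noqa: BLE001 - a failing algorithm is not fatal
            warnings.warn(f"{ts.taxon_id}/{est.algorithm_id} failed: {exc}; excluded")
            continue
        mean_metric = float(np.mean([m[metric] for m in fold_metrics]))
        bounds = None
        if scores is not None:
            calib = ts.calibration_mask & scores.valid_mask
            cells = np.argwhere(calib)
            raw = est.score_samples(scores.features_at(cells))
            surf = np.full(scores.grid_shape, np.nan)
            surf[calib] = raw
            bounds = (float(np.nanmin(surf)), float(np.nanmax(surf)))
            surf = _minmax(surf, bounds)
        else:
            surf = np.full(ts.calibration_mask.shape, np.nan)
        results.append(
            EstimatorResult(est.algorithm_id, fold_metrics, mean_metric, surf, bounds)
        )
    if not results:
        raise RuntimeError(f"{ts.taxon_id}: every algorithm failed")
    return results


def predict_scenario(
    ts: TrainingSet,
    results: list[EstimatorResult],
    registry: list,
    scores: ScoreStack,
) -> list[EstimatorResult]:
    """Re-score retained algorithms on another scenario's axis scores.

    Estimators are refit on the full training data (present-scenario
    features) and applied to the new scenario; metrics carry over from the
    present-scenario evaluation, and so do the present-fit scaling bounds —
    rescaling a future surface by its own extrema would mask an absolute
    loss of suitability.
    """
    by_id = {est.algorithm_id: est for est in registry}
    out = []
    calib = ts.calibration_mask & scores.valid_mask
    cells = np.argwhere(calib)
    feats = scores.features_at(cells)
    for res in results:
        est = by_id[res.algorithm_id]
        est.fit(ts.features, ts.labels)
        raw = est.score_samples(feats)
        surf = np.full(scores.grid_shape, np.nan)
        surf[calib] = raw
        out.append(
            EstimatorResult(
                res.algorithm_id,
                res.fold_metrics,
                res.mean_metric,
                _minmax(surf, res.scale_bounds),
                res.scale_bounds,
            )
        )
    return out


def ensemble(results: list[EstimatorResult], taxon_id: str = "", scenario_id: str = "") -> EnsembleResult:
    """Average the algorithms whose mean metric is at or above the overall mean.

    The >= rule guarantees a non-empty retained set (when all algorithms tie,
    all are retained and the ensemble is the plain mean).
    """
    if not results:
        raise ValueError("need at least one estimator result")
    metrics = np.array([r.mean_metric for r in results])
    # tolerance so a metric exactly at the mean is retained despite FP rounding
    cut = metrics.mean() - 1e-9
    retained = [r for r, m in zip(results, metrics) if m >= cut]
    stack = np.stack([r.suitability for r in retained])
    mean_map = stack.mean(axis=0)
    return EnsembleResult(
        taxon_id,
        scenario_id,
        [r.algorithm_id for r in retained],
        mean_map,
        member_results=list(results),
    )
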