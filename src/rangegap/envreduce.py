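"""Reduction of climate layers to orthogonal axes, projected across scenarios.

Climate variables are strongly collinear, so models are fit on principal
component scores rather than raw layers. The axes — and the per-variable
standardization constants — are estimated on the *present* scenario only and
reused unchanged to project every future scenario, which keeps the predictor
space identical across time and makes present/future suitability directly
comparable. Futures are never re-standardized.

The number of axes kept is the smallest count whose cumulative explained
variance reaches ``variance_target`` (default 0.95).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .grids import ClimateStack

__all__ = ["AxisModel", "ScoreStack", "fit_axes", "project"]


@dataclass
class AxisModel:
    """Fitted axis reduction: standardization constants plus loadings.

    ``loadings`` has shape (n_vars, n_axes_kept) with orthonormal columns;
    scores = ((x - means) / sds) @ loadings. Each column's sign is fixed so
    its largest-magnitude entry is positive, making the fit reproducible
    across linear-algebra backends.
    """

    var_names: list[str]
    means: np.ndarray  # (n_vars,)
    sds: np.ndarray  # (n_vars,)
    loadings: np.ndarray  # (n_vars, n_axes_kept)
    variance_explained: np.ndarray  # all axes, non-increasing
    n_axes_kept: int
    variance_target: float

    def to_json(self, path) -> None:
        payload = {
            "var_names": self.var_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "n_axes_kept": self.n_axes_kept,
            "variance_target": self.variance_target,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AxisModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            var_names=list(d["var_names"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            loadings=np.asarray(d["loadings"]),
            variance_explained=np.asarray(d["variance_explained"]),
            n_axes_kept=int(d["n_axes_kept"]),
            variance_target=float(d["variance_target"]),
        )


@dataclass
class ScoreStack:
    """Per-cell axis scores for one scenario (same grid as the source stack)."""

    scores: np.ndarray  # (n_axes, rows, cols); NaN outside valid_mask
    scenario_id: str
    valid_mask: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.scores.shape[1:]

    @property
    def n_axes(self) -> int:
        return self.scores.shape[0]

    def features_at(self, cells: np.ndarray) -> np.ndarray:
        """(n_records, n_axes) feature matrix at the given (row, col) cells."""
        return self.scores[:, cells[:, 0], cells[:, 1]].T


def fit_axes(present: ClimateStack, variance_target: float = 0.95) -> AxisModel:
    """Fit principal axes on standardized present-scenario values over valid cells.

    Constant layers (zero variance) carry no climatic signal and are dropped
    with a warning before fitting.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    X = present.layers[:, present.valid_mask].T  # (n_cells, n_vars)
    n_cells = X.shape[0]
    if present.n_vars < 2:
        raise ValueError("need at least 2 layers")
    if n_cells < present.n_vars:
        raise ValueError("need at least as many valid cells as variables")

    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        dropped = [v for v, k in zip(present.var_names, keep) if not k]
        warnings.warn(f"dropping constant layers before axis fitting: {dropped}")
    names = [v for v, k in zip(present.var_names, keep) if k]
    X = X[:, keep]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    Z = (X - means) / sds

    # SVD of the standardized data; right singular vectors are the loadings.
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / (n_cells - 1)
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    n_keep = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_keep = min(n_keep, len(ratio))

    loadings = Vt[:n_keep].T  # (n_vars, n_keep)
    # deterministic sign: largest-|.| entry of each column positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_keep)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip

    return AxisModel(
        var_names=names,
        means=means,
        sds=sds,
        loadings=loadings,
        variance_explained=ratio,
        n_axes_kept=n_keep,
        variance_target=variance_target,
    )


def project(stack: ClimateStack, model: AxisModel) -> ScoreStack:
    """Project a scenario onto the fitted axes with the present-fit coefficients."""
    if stack.var_names != model.var_names:
        # constant layers dropped at fit time are tolerated in the stack
        extra = [v for v in stack.var_names if v not in model.var_names]
        missing = [v for v in model.var_names if v not in stack.var_names]
        if missing:
            raise ValueError(f"stack is missing model variables: {missing}")
        if [v for v in stack.var_names if v in model.var_names] != model.var_names:
            raise ValueError("variable order differs from the fitted model")
        if extra:
            warnings.warn(f"ignoring layers unknown to the model: {extra}")
    idx = [stack.var_names.index(v) for v in model.var_names]
    X = stack.layers[idx][:, stack.valid_mask].T
    Z = (X - model.means) / model.sds
    S = Z @ model.loadings  # (n_cells, n_axes)
    scores = np.full((model.n_axes_kept, *stack.grid_shape), np.nan)
    scores[:, stack.valid_mask] = S.T
    return ScoreStack(scores, stack.scenario_id, stack.valid_mask.copy())
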