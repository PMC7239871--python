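"""Weighted-neighbor kNN regression with simulated-annealing variable selection.

Prediction is the weighted average of the k nearest training points in the
Euclidean metric restricted to a selected descriptor subset, with weights
w_i = exp(-d_i).  The subset is chosen by simulated annealing (geometric
cooling) maximizing the leave-one-out q² on the training set; k is searched
over a small range at every objective evaluation.  Distances outside the
selected subset never enter prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ..errors import NanotessError


@dataclass(frozen=True)
class KNNParams:
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    subset_sizes: tuple[int, ...] = (5, 10, 15, 20, 30)
    n_iter: int = 300          # annealing steps per subset size
    t_start: float = 0.05      # initial temperature on the q² scale
    cooling: float = 0.97      # geometric cooling factor per step
    seed: int = 0


def _loo_weighted_predictions(d: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Leave-one-out weighted-kNN predictions given a full distance matrix."""
    n = len(y)
    dd = d.copy()
    np.fill_diagonal(dd, np.inf)
    idx = np.argsort(dd, axis=1, kind="stable")[:, :k]
    nd = np.take_along_axis(dd, idx, axis=1)
    w = np.exp(-nd)
    return (w * y[idx]).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-300)


def _q2(pred: np.ndarray, y: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if np.allclose(pred, y) else 0.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def _best_k(d: np.ndarray, y: np.ndarray, k_range) -> tuple[float, int]:
    best = (-np.inf, k_range[0])
    for k in k_range:
        q2 = _q2(_loo_weighted_predictions(d, y, min(k, len(y) - 1)), y)
        if q2 > best[0]:
            best = (q2, k)
    return best


class KNNModel:
    """Fitted weighted-kNN regressor over a selected descriptor subset."""

    def __init__(self, params: KNNParams | None = None):
        self.params = params or KNNParams()
        self.selected_columns: list[str] | None = None
        self.k: int | None = None

    # -- fitting ---------------------------------------------------------

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "KNNModel":
        params = self.params
        cols = list(X.columns)
        if not cols:
            raise NanotessError("no descriptor columns to select from")
        # requested subset sizes larger than the available columns are capped
        sizes = sorted({min(s, len(cols)) for s in params.subset_sizes})
        rng = np.random.default_rng(params.seed)
        Xv = X.to_numpy(dtype=float)
        yv = y.to_numpy(dtype=float)

        # correlation-guided starting subset: columns most correlated with y
        with np.errstate(invalid="ignore", divide="ignore"):
            xc = Xv - Xv.mean(axis=0)
            yc = yv - yv.mean()
            denom = np.linalg.norm(xc, axis=0) * np.linalg.norm(yc)
            corr = np.abs(np.where(denom > 0, (xc.T @ yc) / np.where(denom > 0, denom, 1), 0.0))
        corr_order = np.argsort(-corr, kind="stable")

        best = None  # (q2, subset tuple, k)
        for size in sizes:
            start = list(corr_order[:size])
            q2, subset, k = self._anneal(Xv, yv, size, rng, start=start)
            if best is None or q2 > best[0]:
                best = (q2, subset, k)
        self.q2_ = best[0]
        self.selected_columns = [cols[i] for i in best[1]]
        self.k = best[2]
        self._train_X = Xv[:, list(best[1])]
        self._train_y = yv
        return self

    def _anneal(self, Xv: np.ndarray, yv: np.ndarray, size: int, rng, start=None):
        n_cols = Xv.shape[1]
        params = self.params
        if start is not None and len(start) == size:
            subset = list(start)
        else:
            subset = list(rng.choice(n_cols, size=size, replace=False))
        score, k = self._objective(Xv, yv, subset)
        best_subset, best_score, best_k = list(subset), score, k
        if size == n_cols:
            return best_score, tuple(best_subset), best_k
        temp = params.t_start
        for _ in range(params.n_iter):
            out_idx = rng.integers(size)
            candidates = np.setdiff1d(np.arange(n_cols), subset)
            new = subset.copy()
            new[out_idx] = int(rng.choice(candidates))
            new_score, new_k = self._objective(Xv, yv, new)
            if new_score > score or rng.random() < np.exp((new_score - score) / max(temp, 1e-12)):
                subset, score, k = new, new_score, new_k
                if score > best_score:
                    best_subset, best_score, best_k = list(subset), score, k
            temp *= params.cooling
        return best_score, tuple(sorted(best_subset)), best_k

    def _objective(self, Xv, yv, subset) -> tuple[float, int]:
        d = cdist(Xv[:, subset], Xv[:, subset])
        return _best_k(d, yv, self.params.k_range)

    # -- prediction ------------------------------------------------------

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if self.selected_columns is None:
            raise NanotessError("model is not fitted")
        if isinstance(X, pd.DataFrame):
            Xq = X[self.selected_columns].to_numpy(dtype=float)
        else:
            Xq = np.asarray(X, dtype=float)
        d = cdist(Xq, self._train_X)
        k = min(self.k, len(self._train_y))
        idx = np.argsort(d, axis=1, kind="stable")[:, :k]
        nd = np.take_along_axis(d, idx, axis=1)
        w = np.exp(-nd)
        return (w * self._train_y[idx]).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-300)
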