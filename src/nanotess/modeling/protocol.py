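"""Dataset containers, the 80/20 + 5-fold protocol, and metric reporting.

R² is the squared Pearson correlation between predicted and experimental
values — the common QSAR convention; the coefficient of determination is
available behind ``evaluate(..., definition="cod")``.  Cross-validation
metrics are computed on the pooled out-of-fold predictions; per-fold metrics
are logged in the report.  Min-max scaling is fitted on the training portion
only and applied to whatever is predicted, so no test information leaks into
fitting or variable selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import NanotessError, SplitError

TRAIN_FRACTION = 0.8
N_FOLDS = 5


@dataclass
class EndpointDataset:
    """Structure ids x descriptor matrix x one measured endpoint."""

    X: pd.DataFrame  # rows indexed by structure id; filtered descriptors
    y: pd.Series  # one value per id
    endpoint: str = "endpoint"
    metadata: dict = field(default_factory=dict)  # e.g. medium, pH, cell line

    def __post_init__(self):
        if not self.X.index.equals(self.y.index):
            self.y = self.y.reindex(self.X.index)
        if self.y.isna().any():
            raise NanotessError("every structure id needs an endpoint value")
        if self.X.isna().any().any():
            raise NanotessError("descriptor matrix contains missing values")

    @property
    def ids(self) -> list:
        return list(self.X.index)

    def __len__(self) -> int:
        return len(self.X)


@dataclass(frozen=True)
class SplitPlan:
    """A seeded 80/20 split and a 5-fold partition of the training ids."""

    seed: int
    train_ids: tuple
    test_ids: tuple
    folds: tuple  # tuple of N_FOLDS id-tuples, disjoint, covering train_ids


def make_split(dataset: EndpointDataset, seed: int) -> SplitPlan:
    """Random 80/20 partition, then round-robin folds over the shuffled train ids.

    The train size is round(0.8 * n); fold sizes differ by at most one.
    """
    n = len(dataset)
    if n < 10:
        raise SplitError(f"need at least 10 structures for modeling, got {n}")
    rng = np.random.default_rng(seed)
    ids = np.array(dataset.ids, dtype=object)
    perm = rng.permutation(n)
    n_train = round(TRAIN_FRACTION * n)
    train = ids[perm[:n_train]]
    test = ids[perm[n_train:]]
    folds = tuple(tuple(train[i::N_FOLDS]) for i in range(N_FOLDS))
    return SplitPlan(seed, tuple(train), tuple(test), folds)


def evaluate(predictions, truth, definition: str = "pearson") -> dict:
    """RMSE and R² of predictions against experimental values.

    ``definition="pearson"`` (default): R² = squared Pearson correlation.
    ``definition="cod"``: coefficient of determination 1 - SS_res/SS_tot.
    Constant truth leaves R² undefined (NaN).
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(truth, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise NanotessError("predictions and truth must be equal-length, size >= 2")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.std(obs) == 0:
        return {"R2": float("nan"), "RMSE": rmse}
    if definition == "pearson":
        if np.std(pred) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
    elif definition == "cod":
        r2 = float(1 - np.sum((obs - pred) ** 2) / np.sum((obs - np.mean(obs)) ** 2))
    else:
        raise ValueError(f"unknown R2 definition {definition!r}")
    return {"R2": r2, "RMSE": rmse}


@dataclass
class ModelReport:
    """Metrics and provenance of one protocol run."""

    endpoint: str
    r2_cv: float
    rmse_cv: float
    r2_val: float
    rmse_val: float
    cv_predictions: pd.Series
    test_predictions: pd.Series
    per_fold: list[dict]
    seed: int
    details: dict = field(default_factory=dict)  # selected subset, history, ...

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "R2_5CV": self.r2_cv, "RMSE_5CV": self.rmse_cv,
            "R2_val": self.r2_val, "RMSE_val": self.rmse_val,
            "per_fold": self.per_fold, "seed": self.seed,
            "details": {k: v for k, v in self.details.items() if _jsonable(v)},
        }


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool, list, tuple, dict, type(None)))


class MinMaxScaler:
    """Train-only min-max scaler (columns with zero range map to 0)."""

    def fit(self, X: pd.DataFrame) -> "MinMaxScaler":
        self.mins = X.min(axis=0)
        self.span = (X.max(axis=0) - self.mins).replace(0, 1.0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.mins) / self.span


def cross_validate(dataset: EndpointDataset, plan: SplitPlan, learner_factory) -> ModelReport:
    """Run the full protocol: 5-fold CV on the train split, then external validation.

    ``learner_factory()`` must return a fresh object with ``fit(X, y)`` and
    ``predict(X)`` (X as DataFrame, y as Series).  Each fold is predicted
    exactly once by a model trained on the other four; external metrics come
    from a model refit on the whole training set.  Scaling is refit on each
    fold's training portion.
    """
    for fold in plan.folds:
        if len(fold) < 2:
            raise SplitError("each fold needs at least 2 points")
    X, y = dataset.X, dataset.y
    oof = {}
    per_fold = []
    for fi, fold in enumerate(plan.folds):
        fold = list(fold)
        fit_ids = [i for f in plan.folds for i in f if i not in set(fold)]
        scaler = MinMaxScaler().fit(X.loc[fit_ids])
        model = learner_factory()
        model.fit(scaler.transform(X.loc[fit_ids]), y.loc[fit_ids])
        pred = model.predict(scaler.transform(X.loc[fold]))
        for i, p in zip(fold, np.asarray(pred, dtype=float)):
            oof[i] = p
        per_fold.append({"fold": fi, **evaluate(pred, y.loc[fold])})

    train_ids = list(plan.train_ids)
    cv_pred = pd.Series({i: oof[i] for i in train_ids})
    cv_metrics = evaluate(cv_pred.to_numpy(), y.loc[train_ids].to_numpy())

    scaler = MinMaxScaler().fit(X.loc[train_ids])
    final = learner_factory()
    final.fit(scaler.transform(X.loc[train_ids]), y.loc[train_ids])
    test_ids = list(plan.test_ids)
    test_pred = pd.Series(
        np.asarray(final.predict(scaler.transform(X.loc[test_ids])), dtype=float),
        index=test_ids,
    )
    val_metrics = evaluate(test_pred.to_numpy(), y.loc[test_ids].to_numpy())

    details = {}
    for attr in ("selected_columns", "k", "history"):
        if hasattr(final, attr):
            details[attr] = getattr(final, attr)
    if not all(np.isfinite(test_pred)):
        raise NanotessError("non-finite external predictions")
    return ModelReport(
        endpoint=dataset.endpoint,
        r2_cv=cv_metrics["R2"], rmse_cv=cv_metrics["RMSE"],
        r2_val=val_metrics["R2"], rmse_val=val_metrics["RMSE"],
        cv_predictions=cv_pred, test_predictions=test_pred,
        per_fold=per_fold, seed=plan.seed, details=details,
    )
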