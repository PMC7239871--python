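"""Property/bioactivity regression under the 80/20 + 5-fold protocol."""

import pandas as pd

from .dnn import DNNModel, DNNParams
from .knn import KNNModel, KNNParams
from .protocol import (
    EndpointDataset,
    MinMaxScaler,
    ModelReport,
    SplitPlan,
    cross_validate,
    evaluate,
    make_split,
)

__all__ = [
    "DNNModel", "DNNParams", "EndpointDataset", "KNNModel", "KNNParams",
    "MinMaxScaler", "ModelReport", "SplitPlan", "cross_validate", "evaluate",
    "make_split", "knn_fit", "knn_predict", "dnn_fit",
]


def knn_fit(X: pd.DataFrame, y: pd.Series, params: KNNParams | None = None) -> KNNModel:
    """Fit a weighted-neighbor kNN model with annealed variable selection."""
    return KNNModel(params).fit(X, y)


def knn_predict(model: KNNModel, X):
    """Weighted-average prediction from the k nearest selected-subset neighbors."""
    return model.predict(X)


def dnn_fit(X: pd.DataFrame, y: pd.Series, params: DNNParams | None = None) -> DNNModel:
    """Train the feedforward network; returns the model with its loss history."""
    return DNNModel(params).fit(X, y)
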