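"""Chemical-space analysis: min-max scaling, pairwise distances, PCA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import NanotessError


@dataclass
class NormalizedMatrix:
    """A descriptor matrix min-max scaled to [0, 1], with inverse-map bounds."""

    data: pd.DataFrame
    mins: pd.Series
    maxs: pd.Series

    def inverse(self) -> pd.DataFrame:
        return self.data * (self.maxs - self.mins) + self.mins


def normalize(matrix: pd.DataFrame) -> NormalizedMatrix:
    """Column-wise (x - min) / (max - min) scaling onto [0, 1].

    Columns with zero range are excluded before scaling.  Normalization uses
    the min/max of the full analyzed set, so similarity thresholds on the
    resulting distances refer to this set's scaling.
    """
    if len(matrix) < 2:
        raise NanotessError("min-max scaling is undefined for a single row")
    mins, maxs = matrix.min(axis=0), matrix.max(axis=0)
    keep = maxs > mins
    cols = matrix.columns[keep]
    scaled = (matrix[cols] - mins[cols]) / (maxs[cols] - mins[cols])
    return NormalizedMatrix(scaled, mins[cols], maxs[cols])


def pairwise_distances(normalized: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    """Exhaustive pairwise Euclidean distances: n(n-1)/2 unordered pairs.

    Returns a 3-column frame (id_i, id_j, distance); summary statistics are
    attached under ``frame.attrs['summary']``.
    """
    data = normalized.data if isinstance(normalized, NormalizedMatrix) else normalized
    n = len(data)
    if n < 2:
        raise NanotessError("need at least 2 rows for pairwise distances")
    ids = list(data.index)
    d = pdist(data.to_numpy(dtype=float))
    pairs = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)]
    frame = pd.DataFrame(pairs, columns=["id_i", "id_j"])
    frame["distance"] = d
    frame.attrs["summary"] = {
        "count": len(d),
        "min": float(d.min()),
        "max": float(d.max()),
        "mean": float(d.mean()),
    }
    return frame


@dataclass
class PCAResult:
    scores: pd.DataFrame  # (n, k) component scores
    explained_variance_ratio: np.ndarray  # length k, non-increasing
    components: np.ndarray  # (k, p) loadings
    mean: np.ndarray


def pca(matrix: NormalizedMatrix | pd.DataFrame, k: int = 3) -> PCAResult:
    """Covariance PCA of the (mean-centered) matrix, top *k* components.

    Component signs follow the convention that each component's
    largest-magnitude loading is positive, making results deterministic.
    """
    data = matrix.data if isinstance(matrix, NormalizedMatrix) else matrix
    n = len(data)
    if not 1 <= k < n:
        raise NanotessError(f"need n > k >= 1, got n={n}, k={k}")
    x = data.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    total = float((s**2).sum())
    evr = (s**2 / total) if total > 0 else np.zeros_like(s)
    scores = pd.DataFrame(
        (u * s)[:, :k], index=data.index, columns=[f"PC{i+1}" for i in range(k)]
    )
    return PCAResult(scores, evr[:k], vt[:k], mean)
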