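"""Distance matrices and agglomerative clustering.

Supports the two dissimilarities the case studies use — Euclidean distance
and Pearson-correlation distance (``1 - r``) — and the three classic
linkages: single (minimum pair distance), complete (maximum), and average
(unweighted mean over cross-cluster pairs, UPGMA).

The merge tree returned by :func:`agglomerate` is already oriented by the
default R-style rules (see :mod:`leafsort.ordering`), so
``order_default(agglomerate(...))`` is a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .treecore import MergeTable, MergeTree, ValidationError, from_merge_table

__all__ = [
    "DistanceMatrix",
    "compute_distance",
    "agglomerate",
    "read_data_matrix",
    "read_distance_matrix",
    "LINKAGES",
    "METRICS",
]

LINKAGES = ("single", "complete", "average")
METRICS = ("euclidean", "pearson")

_SYMMETRY_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities over ``n`` labeled items.

    Validates on construction: square shape, symmetry within 1e-12, exactly
    zero diagonal, no negative or non-finite entries. The stored array is
    exactly symmetrized after validation.
    """

    labels: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} != ({n}, {n})"
            )
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite entries in distance matrix")
        if np.any(self.values < 0):
            raise ValidationError("negative entries in distance matrix")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > _SYMMETRY_TOL:
            raise ValidationError("distance matrix not symmetric within 1e-12")
        self.values = (self.values + self.values.T) / 2.0
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def indices(self, labels) -> np.ndarray:
        try:
            return np.array([self._index[lab] for lab in labels], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"label {exc.args[0]!r} not in distance matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def compute_distance(
    data,
    metric: str = "euclidean",
    labels=None,
    pearson_transform: str = "1-r",
) -> DistanceMatrix:
    """Pairwise dissimilarities between the rows of ``data``.

    Parameters
    ----------
    data : DataFrame or (n, p) array
        Observations in rows, attributes in columns. A DataFrame's index
        supplies the labels.
    metric : {"euclidean", "pearson"}
        ``euclidean`` is the root sum of squared coordinate differences;
        ``pearson`` is ``1 - r`` with ``r`` the sample correlation across
        attributes (requires ``p >= 2`` and per-row variance > 0).
    pearson_transform : {"1-r", "(1-r)/2"}
        ``1 - r`` (range 0..2) is the convention of the common heat-map
        tools; ``(1-r)/2`` rescales to 0..1.
    """
    if isinstance(data, pd.DataFrame):
        if labels is None:
            labels = [str(x) for x in data.index]
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if labels is None:
            labels = [str(i + 1) for i in range(X.shape[0])]
    labels = list(labels)
    n, p = X.shape
    if n < 2:
        raise ValidationError("need at least 2 observations")
    if metric == "euclidean":
        D = squareform(pdist(X, metric="euclidean"))
    elif metric == "pearson":
        if p < 2:
            raise ValidationError("pearson distance requires at least 2 attributes")
        sd = X.std(axis=1)
        bad = np.nonzero(sd == 0)[0]
        if bad.size:
            raise ValidationError(
                f"zero-variance row(s) under pearson distance: {labels[bad[0]]!r}"
            )
        r = np.corrcoef(X)
        D = 1.0 - r
        if pearson_transform == "(1-r)/2":
            D = D / 2.0
        elif pearson_transform != "1-r":
            raise ValidationError(f"unknown pearson transform {pearson_transform!r}")
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2.0, 0.0, None)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels, D)


def agglomerate(dist: DistanceMatrix, linkage: str = "complete") -> MergeTree:
    """Agglomerative hierarchical clustering of a distance matrix.

    At each step the pair of active clusters at minimum dissimilarity is
    merged; ties pick the lexicographically smallest ``(id, id)`` pair, where
    leaves are ``0..n-1`` in input order and merged clusters take ids ``n..``
    in merge order, so runs are fully reproducible. Heights are the
    inter-cluster dissimilarity at each merge, maintained with the
    Lance–Williams update for the chosen linkage.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}")
    n = len(dist)
    if n < 2:
        raise ValidationError("need at least 2 items to cluster")
    m = 2 * n - 1
    W = np.full((m, m), np.inf)
    W[:n, :n] = dist.values
    np.fill_diagonal(W, np.inf)
    W[np.tril_indices(m)] = np.inf  # search upper triangle: i < j
    sizes = np.zeros(m)
    sizes[:n] = 1
    active = np.zeros(m, dtype=bool)
    active[:n] = True
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        flat = int(np.argmin(W))  # row-major: smallest i, then smallest j
        i, j = divmod(flat, m)
        h = W[i, j]
        new = n + step
        others = np.nonzero(active)[0]
        others = others[(others != i) & (others != j)]
        di = np.where(others < i, W[others, i], W[i, others])
        dj = np.where(others < j, W[others, j], W[j, others])
        if linkage == "single":
            dn = np.minimum(di, dj)
        elif linkage == "complete":
            dn = np.maximum(di, dj)
        else:
            dn = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
        W[others, new] = dn
        W[i, :] = np.inf
        W[:, i] = np.inf
        W[j, :] = np.inf
        W[:, j] = np.inf
        sizes[new] = sizes[i] + sizes[j]
        active[i] = active[j] = False
        active[new] = True
        merges.append((i, j, float(h)))
    tree = from_merge_table(MergeTable(merges, list(dist.labels)))
    from .ordering import order_default

    return order_default(tree)


# -- text interchange -------------------------------------------------------

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_data_matrix(path) -> pd.DataFrame:
    """Read a labeled numeric matrix: header row of attribute names, first
    column of observation labels."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] < 1:
        raise ValidationError(f"{path}: no attribute columns")
    df.index = df.index.map(str)
    return df.astype(float)


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square labeled distance matrix; row and column labels must match."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row labels do not match column labels")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))
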