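"""Bundled datasets and synthetic generators.

Everything here runs offline: the Iris table comes from scikit-learn's
local copy, and the simulated sets are produced programmatically from a
seed. The two-dimensional Gaussian-cluster generator emulates the kind of
simulated point set the ordering case studies are run on — a handful of
well-separated isotropic clusters whose within-cluster spread controls how
tight each merge is.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .treecore import ValidationError

__all__ = ["make_gaussian_clusters", "fig2_toy", "load_iris"]


def make_gaussian_clusters(
    k: int = 3,
    n_per: int = 12,
    dim: int = 2,
    sep: float = 10.0,
    sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[int]]:
    """Isotropic Gaussian clusters on a grid of centers.

    Returns ``(data, cluster_ids)``: a ``k * n_per`` x ``dim`` DataFrame with
    rows labeled ``"1" .. "k*n_per"`` in input order (cluster blocks
    contiguous), and the true cluster id (1-based) per row. Centers sit on an
    integer grid scaled by ``sep``; noise is N(0, sd^2) per coordinate.
    Defaults give 3 clusters of 12 points in 2-D at separation 10 with unit
    spread — comfortably separated but with visible within-cluster structure.
    """
    if k < 1 or n_per < 1 or dim < 1:
        raise ValidationError("k, n_per and dim must all be >= 1")
    if sd <= 0 or sep < 0:
        raise ValidationError("sd must be > 0 and sep >= 0")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(k ** (1.0 / dim)))
    grid = list(itertools.product(range(side), repeat=dim))[:k]
    centers = np.array(grid, dtype=float) * sep
    rows = np.repeat(centers, n_per, axis=0) + rng.normal(0.0, sd, (k * n_per, dim))
    labels = [str(i + 1) for i in range(k * n_per)]
    cols = [f"x{d + 1}" for d in range(dim)]
    truth = [c + 1 for c in range(k) for _ in range(n_per)]
    return pd.DataFrame(rows, index=labels, columns=cols), truth


# Ten 2-D points engineered so that complete-linkage clustering exercises
# every orientation rule in one tree: four leaf-leaf merges, two
# leaf-subtree merges, and three subtree-subtree merges. The coordinates are
# this package's own; labels "1".."10" double as the input order.
_TOY_POINTS = [
    (0.0, 0.0),    # 1  \ tightest pair
    (0.5, 0.0),    # 2  /
    (2.5, 0.0),    # 3  leaf joining the {1,2} pair
    (10.0, 0.0),   # 4  \ second pair
    (10.6, 0.0),   # 5  /
    (12.4, 0.0),   # 6  leaf joining the {4,5} pair
    (20.0, 5.0),   # 7  \ third pair
    (20.8, 5.0),   # 8  /
    (24.0, 5.0),   # 9  \ fourth pair
    (24.9, 5.0),   # 10 /
]


def fig2_toy() -> pd.DataFrame:
    """A fixed 10-point, 2-D demonstration set (labels ``"1".."10"`` in
    input order) whose complete-linkage dendrogram contains all three merge
    types, so the default and modular orientation rules can all be seen in a
    single small tree. Deterministic: the coordinates are literals."""
    return pd.DataFrame(
        _TOY_POINTS,
        index=[str(i + 1) for i in range(10)],
        columns=["x", "y"],
    )


def load_iris() -> tuple[pd.DataFrame, list[str]]:
    """The classic 150-flower iris morphometry table: 4 measurements
    (sepal length/width, petal length/width, cm) for 50 flowers of each of
    three species. Rows are labeled ``"1".."150"`` in the canonical order
    (species blocks of 50). Returns ``(data, species)``."""
    from sklearn.datasets import load_iris as _sk_iris

    bunch = _sk_iris()
    cols = ["sepal_length", "sepal_width", "petal_length", "petal_width"]
    df = pd.DataFrame(
        bunch.data,
        index=[str(i + 1) for i in range(bunch.data.shape[0])],
        columns=cols,
    )
    species = [str(bunch.target_names[t]) for t in bunch.target]
    return df, species
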