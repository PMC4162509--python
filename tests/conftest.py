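import numpy as np
import pytest

from leafsort import DistanceMatrix, MergeTable, from_merge_table


def random_tree(rng, n, monotone=True):
    """Random merge tree over labels L1..Ln (input indices 0..n-1).

    Builds a random agglomeration: repeatedly merge two random active
    clusters at a height drawn as a cumulative positive increment (monotone)
    or an independent uniform draw (non-monotone).
    """
    merges = []
    active = list(range(n))
    h = 0.0
    for step in range(n - 1):
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        if monotone:
            h += float(rng.uniform(0.1, 1.0))
        else:
            h = float(rng.uniform(0.1, 10.0))
        merges.append((a, b, h))
        del active[j], active[i]
        active.append(n + step)
    return from_merge_table(MergeTable(merges, [f"L{i+1}" for i in range(n)]))


def random_dist(rng, labels):
    """Random symmetric distance matrix with distinct off-diagonal entries."""
    n = len(labels)
    M = rng.uniform(0.5, 10.0, (n, n))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 0.0)
    return DistanceMatrix(list(labels), M)


def naive_agglomerate(dist, linkage):
    """From-scratch O(n^3) agglomeration: cluster distances recomputed from
    the original matrix at every step (no Lance-Williams update). Ties pick
    the lexicographically smallest (id, id) pair. Returns the list of merges
    as (leaf-label frozenset, height)."""
    D = dist.values
    clusters = [(i, frozenset([i])) for i in range(len(dist))]
    next_id = len(dist)
    out = []
    for _ in range(len(dist) - 1):
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                ia, sa = clusters[x]
                ib, sb = clusters[y]
                pair = [D[p, q] for p in sa for q in sb]
                if linkage == "single":
                    d = min(pair)
                elif linkage == "complete":
                    d = max(pair)
                else:
                    d = sum(pair) / len(pair)
                key = (d, min(ia, ib), max(ia, ib))
                if best is None or key < best[0]:
                    best = (key, x, y)
        (d, _, _), x, y = best
        _, sa = clusters[x]
        _, sb = clusters[y]
        merged = sa | sb
        out.append((frozenset(dist.labels[i] for i in merged), d))
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append((next_id, merged))
        next_id += 1
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240730)
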