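# Methods

## The ordering problem

Agglomerative hierarchical clustering of `n` items produces a binary merge
tree: `n − 1` merges, each at a height equal to the inter-cluster
dissimilarity at which it happened. Drawing that tree, and reordering a
matrix by it, requires choosing a left/right orientation at every merge;
the `2^(n−1)` resulting leaf orders are all equally faithful to the
clustering. The orderings implemented here differ in what they optimize:

* **default** reproduces the R-style convention: a leaf-leaf merge follows
  input-matrix order; a leaf merging with a subtree goes left; of two
  subtrees, the one formed at the smaller height goes left.
* **molo-min / molo-avg** (modular leaf ordering) assign each subtree a
  *key* — the minimum, or the arithmetic mean, of all merge heights inside
  it — with leaves carrying the sentinel `+inf`, and swap children wherever
  `key(left) > key(right)`. The sentinel makes the leaf-goes-right rule a
  corollary of the key comparison and settles the leaf-vs-leaf case (both
  keys infinite → tie → keep the current orientation, i.e. input order when
  starting from the default). Each subtree then reads left to right in the
  order its clusters were merged and is drawn as a right triangle; the
  tightest (or lowest-mean) cluster is leftmost. The `avg` variant exists
  for loose clusters that contain a single tight pair: a subtree whose
  smallest height is tiny but whose remaining merges are long has a small
  min-key but a large mean-key, so `avg` pushes it rightward.
* **gw** (Gruvaeus–Wainer) is the greedy bottom-up endpoint heuristic: each
  subtree reports its outermost leaves, and at every merge the four flip
  combinations are scored by the distance between the two leaves that end
  up adjacent across the merge; the minimum wins, with ties preferring no
  flip, then a left-child flip, then right, then both.
* **olo** (optimal leaf ordering) minimizes the Hamiltonian path length
  `Σ d(o_i, o_{i+1})` exactly over all flip orders, by dynamic programming
  over states (subtree, leftmost leaf, rightmost leaf):
  `cost(V, l, r) = min_{m,k} cost(L, l, m) + d(m, k) + cost(R, k, r)`.
  The min-plus products are evaluated with chunked numpy broadcasting, so
  memory stays bounded (~32 MB of scratch) on large trees; the size cap
  (default `n = 2000`) guards the cubic running time. Ties at the root
  resolve toward the input orientation.

Every operation returns a reoriented copy; topology and heights are
untouched, every tie keeps the existing orientation, and therefore every
method is deterministic. `order_molo` is idempotent because subtree keys
are set statistics, unaffected by orientation.

## Metrics

**Line length.** The layout convention is fixed so that "ink" is
well-defined: leaves at positions `1..n` with unit spacing, heights in raw
dissimilarity units, each internal node at the x-midpoint of its children,
and per merge one horizontal connector plus two vertical risers down to
the children's heights. The riser total depends only on the multiset of
(parent, child) height pairs, so it is identical across all orientations
of a tree — any ink difference between orderings is purely in the
connectors. Because the absolute total depends on the (arbitrary) ratio of
the two axis units, the scale-invariant **data-ink ratio** relative to the
default orientation is the primary comparison surface.

**Hamiltonian path length** is the seriation loss `olo` minimizes.

**Anti-Robinson events** are counted per ordered triple `i < j < k`, two
sided and unweighted: one event if `d(o_i,o_j) > d(o_i,o_k)`, one if
`d(o_j,o_k) > d(o_i,o_k)`. This is the plain definitional count (the
concept is often cited without a formula); it is invariant under order
reversal and zero exactly for a Robinson-form reordered matrix.

## Clustering

Distances: Euclidean, or Pearson distance `1 − r` across attributes
(configurable to `(1 − r)/2`; `1 − r` is the convention of the common
heat-map tools). Linkages: single, complete, and average, where average is
the unweighted mean over cross-cluster pairs (UPGMA), maintained by the
Lance–Williams recurrence. Ties in the minimum-distance search merge the
lexicographically smallest (id, id) pair — leaves numbered `0..n-1` in
input order, merged clusters `n..` in merge order — so every run is
reproducible bit for bit. The returned tree is already in the default
orientation, making `order_default` a fixed point of `agglomerate`.
Complete and average linkage yield monotone height sequences; single
linkage can tie, which `validate` reports rather than rejects. The
implementation is cross-checked in the tests against both an independent
from-scratch O(n³) reference (cluster distances recomputed from the
original matrix at every step) and scipy's linkage heights.

## Synthetic data and fixtures

`make_gaussian_clusters` draws `k` isotropic Gaussian clusters of `n_per`
points on an integer grid of centers scaled by `sep`, with within-cluster
standard deviation `sd`, fully determined by its seed. Defaults —
`k=3, n_per=12, dim=2, sep=10, sd=1` — give 36 points in three clearly
separated groups with visible within-cluster structure, the regime the
linkage-comparison experiments are run in. The generator emulates
well-separated low-dimensional point clouds; it does not produce
correlated attributes, outliers, nested cluster hierarchies, or the
high-dimensional noise of real expression matrices, so passing tests
demonstrate correctness of the ordering machinery, not robustness of
clustering on messy data.

`fig2_toy` is a fixed, hand-placed 10-point 2-D configuration (a tight
pair joined by a leaf, a second such triple, and two more pairs) whose
complete-linkage tree contains all three merge types, so every orientation
rule is exercised in a single small tree. Its coordinates are this
package's own engineered stand-in for that kind of demonstration set.

`load_iris` returns the classic 150 × 4 iris morphometry table (50 flowers
per species) from scikit-learn's bundled copy — no download, deterministic.

The heat-map demonstration for association matrices (rows scored in
[−1, 1], Pearson distance, complete linkage) runs on synthetic matrices
generated in the tests; the original pathway-association table is not
redistributed with this package.

## Numerical and design choices

* Heights are stored on nodes; Newick serialization converts to edge
  lengths (`parent height − child height`) at 12 significant digits, and
  parsing (via Bio.Phylo) reconstructs heights from root depths, snapping
  leaves to height 0. Non-ultrametric or non-monotone input is surfaced by
  `validate` as a diagnostic, not an error, since single-linkage ties and
  external trees may be legitimately non-strict.
* Zero-height merges (duplicate observations) are permitted and flagged by
  `validate`; negative or non-finite heights are hard errors.
* Flattening a tree to a merge table orders rows by height under the
  child-before-parent constraint (a height-keyed topological sort), which
  for monotone trees is exactly merge order and keeps tied rows stable.
* The SVG renderer shares the metrics module's geometry (leaf slots, node
  at children's midpoint, one connector + two risers per merge), formats
  all coordinates to two decimals, and orders elements deterministically,
  so identical inputs give byte-identical documents. In limited display
  space, leaf labels are dropped once the per-leaf slot falls below a
  threshold (default 4 px) instead of overplotting.
* The diverging heat-map palette is blue-white-red with explicit limits
  (symmetric about zero when the data straddle zero); the annotation strip
  uses a fixed categorical palette assigned to sorted category names.

## Problem sizes

The test suite runs at desk scale by design: exhaustive flip enumeration
(the oracle for `olo`, `gw`, and the ink decomposition) up to `n = 10`,
the from-scratch linkage reference up to `n = 15`, structural guarantees
on random trees up to `n = 200`, and the full iris pipeline at `n = 150`.
The acceptance script reuses the iris case study and the generator
defaults (`n = 36`).

## Known limitations

* Only strictly binary trees with heights are supported — no
  multifurcations, no cladograms.
* `olo` is exact but cubic; beyond the configured cap the modular or GW
  heuristics are the intended fallback.
* Ward/centroid/median linkage and unconstrained (non-tree) seriation are
  out of scope, as are raster export and interactive viewers.
* Absolute line-length totals depend on the layout's unit convention;
  comparisons across packages should use the ink *ratio*, which is
  invariant to uniform rescaling of either axis.
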