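"""Ordering heuristics: rule-by-rule examples plus oracle equivalence."""

import math

import numpy as np
import pytest

import leafsort as ls
from leafsort import DistanceMatrix, MergeTable, ValidationError
from leafsort.treecore import MergeTree, Node

from conftest import random_dist, random_tree


def tree_of(merges, labels):
    return ls.from_merge_table(MergeTable(merges, list(labels)))


def dist_of(labels, pairs):
    n = len(labels)
    M = np.zeros((n, n))
    for (a, b), v in pairs.items():
        i, j = labels.index(a), labels.index(b)
        M[i, j] = M[j, i] = v
    return DistanceMatrix(list(labels), M)


class TestOrderDefault:
    def test_leaf_leaf_uses_input_order(self):
        # leaves with input indices 7 and 3: index 3 goes left
        a = Node(7, label="H", index=7)
        b = Node(3, label="D", index=3)
        t = ls.order_default(MergeTree(Node(10, 1.0, a, b)))
        assert ls.leaf_order(t) == ["D", "H"]

    def test_leaf_goes_left_of_subtree(self):
        pair = Node(3, 1.0, Node(0, label="L1", index=0), Node(1, label="L2", index=1))
        t = MergeTree(Node(4, 3.0, pair, Node(2, label="L5", index=2)))
        assert ls.leaf_order(ls.order_default(t)) == ["L5", "L1", "L2"]

    def test_smaller_previous_merge_goes_left(self):
        # subtree heights 2.0 vs 1.0: the height-1.0 subtree goes left
        t = tree_of([(0, 1, 2.0), (2, 3, 1.0), (4, 5, 5.0)], "ABCD")
        assert ls.leaf_order(ls.order_default(t)) == ["C", "D", "A", "B"]

    def test_missing_indices_rejected(self):
        t = MergeTree(Node(2, 1.0, Node(0, label="A"), Node(1, label="B")))
        with pytest.raises(ValidationError, match="indices"):
            ls.order_default(t)


class TestOrderMolo:
    def test_min_criterion_sorts_subtree_minima(self):
        t = tree_of([(0, 1, 2.0), (2, 3, 1.0), (4, 5, 5.0)], "CDAB")
        assert ls.leaf_order(ls.order_molo(t, "min")) == ["A", "B", "C", "D"]

    def test_leaf_goes_right_of_subtree(self):
        pair = Node(3, 1.0, Node(0, label="A", index=0), Node(1, label="B", index=1))
        t = MergeTree(Node(4, 3.0, Node(2, label="E", index=2), pair))
        assert ls.leaf_order(ls.order_molo(t)) == ["A", "B", "E"]

    def test_min_and_avg_criteria_diverge(self):
        # S1 merge heights {1, 4} (min 1, avg 2.5); S2 height {2} (min 2, avg 2)
        merges = [(0, 1, 1.0), (5, 2, 4.0), (3, 4, 2.0), (6, 7, 8.0)]
        t = tree_of(merges, "ABCDE")
        assert ls.leaf_order(ls.order_molo(t, "min"))[:3] == ["A", "B", "C"]
        assert ls.leaf_order(ls.order_molo(t, "avg"))[:2] == ["D", "E"]

    def test_leaf_key_is_infinite(self):
        assert ls.ordering.subtree_key(Node(0, label="A")) == math.inf

    @pytest.mark.parametrize("criterion", ["min", "avg"])
    def test_postcondition_and_idempotence(self, rng, criterion):
        for _ in range(10):
            n = int(rng.integers(2, 40))
            t = ls.order_molo(random_tree(rng, n, monotone=False), criterion)
            for node in t.internal_nodes():
                assert (
                    ls.ordering.subtree_key(node.left, criterion)
                    <= ls.ordering.subtree_key(node.right, criterion)
                )
            assert ls.leaf_order(ls.order_molo(t, criterion)) == ls.leaf_order(t)

    def test_tightest_cluster_on_leftmost_descent(self, rng):
        # the minimum-height merge is reachable from the root by walking left
        for _ in range(10):
            t = ls.order_molo(random_tree(rng, 30))
            lo = min(n.height for n in t.internal_nodes())
            node = t.root
            chain = []
            while not node.is_leaf:
                chain.append(node.height)
                node = node.left
            assert lo in chain

    def test_unknown_criterion(self):
        with pytest.raises(ValidationError, match="criterion"):
            ls.order_molo(tree_of([(0, 1, 1.0)], "AB"), "median")


GW_4 = dist_of(list("ABCD"), {("A", "B"): 1, ("C", "D"): 2, ("B", "C"): 3,
                              ("B", "D"): 4, ("A", "C"): 4, ("A", "D"): 5})


class TestOrderGW:
    def test_inner_pair_minimal_four_leaves(self):
        t = tree_of([(0, 1, 1.0), (2, 3, 2.0), (4, 5, 5.0)], "ABCD")
        assert ls.leaf_order(ls.order_gw(t, GW_4)) == ["A", "B", "C", "D"]

    def test_leaf_adjacent_to_closest_endpoint(self):
        d = dist_of(list("ABC"), {("A", "B"): 1, ("A", "C"): 4, ("B", "C"): 3})
        t = tree_of([(0, 1, 1.0), (3, 2, 4.0)], "ABC")
        assert ls.leaf_order(ls.order_gw(t, d)) == ["A", "B", "C"]

    def test_two_leaf_tie_keeps_orientation(self):
        d = dist_of(["A", "B"], {("A", "B"): 2.0})
        t = tree_of([(0, 1, 2.0)], "AB")
        assert ls.leaf_order(ls.order_gw(t, d)) == ["A", "B"]

    def test_chosen_inner_pair_is_nodewise_minimal(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 20))
            labels = [f"L{i+1}" for i in range(n)]
            d = random_dist(rng, labels)
            t = ls.order_gw(random_tree(rng, n), d)
            for node in t.internal_nodes():
                lL, rL = _endpoints(node.left)
                lR, rR = _endpoints(node.right)
                chosen = d.get(rL, lR)
                assert chosen <= min(d.get(lL, lR), d.get(rL, rR), d.get(lL, rR))

    def test_missing_label_rejected(self):
        t = tree_of([(0, 1, 1.0)], ["A", "Z"])
        with pytest.raises(ValidationError, match="Z"):
            ls.order_gw(t, GW_4)


def _endpoints(node):
    order = [l.label for l in _leaves(node)]
    return order[0], order[-1]


def _leaves(node):
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            yield cur
        else:
            stack.extend((cur.right, cur.left))


class TestOrderOLO:
    def test_four_leaf_example(self):
        t = tree_of([(0, 1, 1.0), (2, 3, 2.0), (4, 5, 5.0)], "ABCD")
        ordered = ls.order_olo(t, GW_4)
        assert ls.leaf_order(ordered) == ["A", "B", "C", "D"]
        assert ls.path_length(GW_4, ls.leaf_order(ordered)) == pytest.approx(6.0)

    def test_two_leaf_unchanged(self):
        d = dist_of(["A", "B"], {("A", "B"): 1.5})
        t = tree_of([(0, 1, 1.5)], "AB")
        assert ls.leaf_order(ls.order_olo(t, d)) == ["A", "B"]

    def test_equals_exhaustive_minimum(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 11))
            labels = [f"L{i+1}" for i in range(n)]
            d = random_dist(rng, labels)
            t = random_tree(rng, n)
            got = ls.path_length(d, ls.leaf_order(ls.order_olo(t, d)))
            best = min(
                ls.path_length(d, o) for o in ls.enumerate_flip_orders(t)
            )
            assert got == pytest.approx(best, rel=1e-9)

    def test_cap_exceeded(self):
        t = random_tree(np.random.default_rng(0), 12)
        d = random_dist(np.random.default_rng(1), [f"L{i+1}" for i in range(12)])
        with pytest.raises(ls.LeafsortError, match="molo"):
            ls.order_olo(t, d, cap=10)


class TestEnumerateFlipOrders:
    @pytest.mark.parametrize("n, count", [(2, 2), (4, 8), (10, 512)])
    def test_counts(self, rng, n, count):
        orders = ls.enumerate_flip_orders(random_tree(rng, n))
        assert len(orders) == count
        assert len(set(orders)) == count  # all distinct with unique labels

    def test_guard(self, rng):
        with pytest.raises(ls.LeafsortError, match="guard"):
            ls.enumerate_flip_orders(random_tree(rng, 17))


class TestDispatch:
    def test_all_methods_preserve_structure(self, rng):
        n = 30
        labels = [f"L{i+1}" for i in range(n)]
        d = random_dist(rng, labels)
        t = ls.agglomerate(d, "average")
        want = ls.subtree_profile(t)
        for method in ls.ORDER_METHODS:
            assert ls.subtree_profile(ls.order_by_method(t, method, d)) == want

    def test_gw_requires_distances(self, rng):
        with pytest.raises(ValidationError, match="distance"):
            ls.order_by_method(random_tree(rng, 5), "gw")

    def test_unknown_method(self, rng):
        with pytest.raises(ValidationError, match="unknown"):
            ls.order_by_method(random_tree(rng, 5), "bogus")
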