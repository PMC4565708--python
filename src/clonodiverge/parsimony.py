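"""Exact maximum parsimony on binary taxon matrices.

Tree length is Fitch parsimony (unordered, equally weighted, reversible
states) computed by the two-pass set-intersection algorithm on an
arbitrary rooting.  The search is exact: stepwise taxon addition visits
every unrooted binary topology at most once, pruning partial trees whose
length plus an admissible lower bound (one change for every character
state not yet attached) exceeds the best complete length.  All
most-parsimonious trees are returned, their strict consensus contains
exactly the splits common to all of them, and the consensus can be
anchor-rooted between two named clades.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .data_io import BinaryTaxonMatrix, Tree, TreeNode, ValidationError

__all__ = [
    "TreeSet",
    "fitch_score",
    "branch_and_bound",
    "mp_consensus",
    "strict_consensus",
    "root_between",
]


@dataclass
class TreeSet:
    """All most-parsimonious trees for a matrix, and their common length."""

    trees: list[Tree]
    score: int

    def __len__(self) -> int:
        return len(self.trees)

    def split_sets(self) -> list[frozenset]:
        return [t.splits() for t in self.trees]


# ---------------------------------------------------------------------------
# Fitch length


def _state_masks(matrix: BinaryTaxonMatrix) -> dict[str, np.ndarray]:
    """Per-taxon bitmask vectors: state 0 → 1, state 1 → 2."""
    return {
        t: (matrix.states[i] + 1).astype(np.uint8)
        for i, t in enumerate(matrix.taxa)
    }


def fitch_score(tree: Tree, matrix: BinaryTaxonMatrix) -> int:
    """Minimum number of state changes of all characters on the tree.

    Two-pass (bottom-up) Fitch on the tree as stored; the result is
    independent of the rooting for binary (bifurcating) trees.  Node
    children are combined pairwise in order, which is exact for
    bifurcations; multifurcating consensus trees get an upper bound of
    their Hartigan length, which is adequate here because scoring is only
    contractually defined on binary trees.
    """
    if tree.leaves != frozenset(matrix.taxa):
        raise ValidationError("tree leaves do not match matrix taxa")
    masks = _state_masks(matrix)
    score = 0

    def walk(node: TreeNode) -> np.ndarray:
        nonlocal score
        if node.is_leaf:
            return masks[node.label]
        acc = walk(node.children[0])
        for child in node.children[1:]:
            m = walk(child)
            inter = acc & m
            empty = inter == 0
            score += int(empty.sum())
            acc = np.where(empty, acc | m, inter)
        return acc

    walk(tree.root)
    return score


# ---------------------------------------------------------------------------
# branch and bound

class _Node:
    __slots__ = ("label", "left", "right", "parent")

    def __init__(self, label: Optional[int] = None):
        self.label = label  # taxon index for leaves
        self.left: Optional["_Node"] = None
        self.right: Optional["_Node"] = None
        self.parent: Optional["_Node"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _pack_masks(states: np.ndarray) -> tuple[list[int], int]:
    """Pack each taxon's character states into one integer of 2-bit fields.

    State 0 → field 01, state 1 → field 10; Fitch set operations become
    plain bitwise arithmetic on Python integers, which keeps the inner
    search loop allocation-free.  Returns the masks and the unit mask
    (bit 0 of every field).
    """
    n, m = states.shape
    unit = sum(1 << (2 * c) for c in range(m))
    masks = [
        sum((int(states[i, c]) + 1) << (2 * c) for c in range(m))
        for i in range(n)
    ]
    return masks, unit


class _Search:
    """Stepwise-addition enumeration of unrooted binary trees with pruning.

    The unrooted tree on taxa 0..k−1 is held as a binary tree rooted on the
    pendant edge of taxon 0: ``root`` has children [leaf 0, rest].  Taxon k
    can be inserted on the parent edge of any node except the root and leaf
    0, which enumerates the 2k−3 unrooted edges exactly once, so every
    topology is generated exactly once.
    """

    def __init__(self, states: np.ndarray, prune: bool = True,
                 max_trees: Optional[int] = None):
        self.masks, self.unit = _pack_masks(states)
        self.n = states.shape[0]
        self.prune = prune
        self.max_trees = max_trees
        # extra changes guaranteed by taxa >= k: states absent from taxa < k
        n = self.n
        full = (self.unit << 1) | self.unit
        suffix = [0] * (n + 1)
        for k in range(n - 1, -1, -1):
            suffix[k] = suffix[k + 1] | self.masks[k]
        prefix = [0] * (n + 1)
        for k in range(1, n + 1):
            prefix[k] = prefix[k - 1] | self.masks[k - 1]
        self.remaining = [
            self._field_count(suffix[k] & ~prefix[k] & full)
            for k in range(n + 1)
        ]
        self.best = np.inf
        self.results: list = []

    def _field_count(self, m: int) -> int:
        return ((m & self.unit) | ((m >> 1) & self.unit)).bit_count()

    # -- scoring -----------------------------------------------------------
    def _score(self, root: _Node) -> int:
        unit = self.unit
        masks = self.masks
        score = 0

        def walk(node: _Node) -> int:
            nonlocal score
            if node.left is None:
                return masks[node.label]
            a = walk(node.left)
            b = walk(node.right)
            i = a & b
            e = unit ^ ((i | (i >> 1)) & unit)
            if e:
                score += e.bit_count()
                return i | ((e | (e << 1)) & (a | b))
            return i

        a = walk(root.left)
        b = walk(root.right)
        i = a & b
        score += (unit ^ ((i | (i >> 1)) & unit)).bit_count()
        return score

    # -- tree surgery ------------------------------------------------------
    @staticmethod
    def _insert(node: _Node, leaf: _Node) -> _Node:
        new = _Node()
        parent = node.parent
        if parent.left is node:
            parent.left = new
        else:
            parent.right = new
        new.parent = parent
        new.left, new.right = node, leaf
        node.parent = new
        leaf.parent = new
        return new

    @staticmethod
    def _remove(new: _Node) -> None:
        node = new.left
        parent = new.parent
        if parent.left is new:
            parent.left = node
        else:
            parent.right = node
        node.parent = parent

    @staticmethod
    def _edges(root: _Node) -> list[_Node]:
        """Nodes whose parent edge is an insertable unrooted edge."""
        out: list[_Node] = []
        stack = [root.right]  # skip the root and leaf 0 (root.left)
        while stack:
            n = stack.pop()
            out.append(n)
            if not n.is_leaf:
                stack.append(n.left)
                stack.append(n.right)
        return out

    # -- recursion ---------------------------------------------------------
    def run(self, collect: str = "trees") -> tuple[list, int]:
        """DFS over all topologies; ``collect`` is "trees" or "splits".

        In "splits" mode no tree is materialized: the running
        intersection of optimal split sets (leaf-index bitmasks) and the
        optimal-tree count are maintained instead, so degenerate tie
        structures with astronomically many equally short trees stay
        tractable.
        """
        if self.n < 3:
            raise ValidationError("parsimony search needs ≥3 taxa")
        self.collect = collect
        self.n_opt = 0
        self.split_intersection: Optional[set] = None
        root = _Node()
        leaves = [_Node(i) for i in range(self.n)]
        inner = _Node()
        root.left, root.right = leaves[0], inner
        leaves[0].parent = inner.parent = root
        inner.left, inner.right = leaves[1], leaves[2]
        leaves[1].parent = leaves[2].parent = inner
        if self.prune:
            self.best = self._greedy_bound(root, leaves)
        self._recurse(root, leaves, 3)
        return self.results, int(self.best)

    def _splits_of(self, root: _Node) -> set:
        """Nontrivial splits of the current topology as leaf-index bitmasks.

        Canonical side = the one not containing taxon 0 (the root leaf).
        """
        n = self.n
        full = (1 << n) - 1
        out: set[int] = set()

        def walk(node: _Node) -> int:
            if node.left is None:
                return 1 << node.label
            m = walk(node.left) | walk(node.right)
            if 2 <= m.bit_count() <= n - 2:
                out.add(m)  # never contains taxon 0: it sits on the root edge
            return m

        walk(root.right)
        return out

    def _greedy_bound(self, root: _Node, leaves: list[_Node]) -> float:
        """Length of a greedy addition tree — initial upper bound."""
        for k in range(3, self.n):
            best_edge, best_s = None, np.inf
            for edge in self._edges(root):
                new = self._insert(edge, leaves[k])
                s = self._score(root)
                self._remove(new)
                leaves[k].parent = None
                if s < best_s:
                    best_s, best_edge = s, edge
            self._insert(best_edge, leaves[k])
        score = self._score(root)
        for k in range(self.n - 1, 2, -1):
            self._remove(leaves[k].parent)
            leaves[k].parent = None
        return score

    def _record(self, root: _Node, score: int) -> None:
        if score < self.best:
            self.best = score
            self.results = []
            self.n_opt = 0
            self.split_intersection = None
        self.n_opt += 1
        if self.collect == "splits":
            s = self._splits_of(root)
            if self.split_intersection is None:
                self.split_intersection = s
            else:
                self.split_intersection &= s
            return
        self.results.append(_edgelist(root))
        if self.max_trees is not None and len(self.results) > self.max_trees:
            raise ValidationError(
                f"more than {self.max_trees} most-parsimonious trees"
            )

    def _recurse(self, root: _Node, leaves: list[_Node], k: int) -> None:
        if k == self.n:
            s = self._score(root)
            if s <= self.best:
                self._record(root, s)
            return
        for edge in self._edges(root):
            new = self._insert(edge, leaves[k])
            s = self._score(root)
            if not self.prune or s + self.remaining[k + 1] <= self.best:
                self._recurse(root, leaves, k + 1)
            self._remove(new)
            leaves[k].parent = None


def _edgelist(root: _Node):
    """Frozen copy of the current topology as nested tuples of taxon indices."""

    def ser(node: _Node):
        if node.is_leaf:
            return node.label
        return (ser(node.left), ser(node.right))

    return (ser(root.left), ser(root.right))


def _nested_to_tree(nested, labels: Sequence[str]) -> Tree:
    """Convert the frozen nested-tuple form to an unrooted Tree.

    The stored form is (leaf0, rest); the returned tree uses the
    conventional basal trifurcation obtained by collapsing the degree-2
    basal node.
    """
    def build(x) -> TreeNode:
        if isinstance(x, int):
            return TreeNode(label=labels[x])
        return TreeNode(children=[build(x[0]), build(x[1])])

    left, right = nested
    base = build(right)
    first = build(left)
    if base.is_leaf:
        root = TreeNode(children=[first, base])
    else:
        root = TreeNode(children=[first] + base.children)
    return Tree(root, rooted=False)


def _addition_order(states: np.ndarray, taxa: Sequence[str]) -> list[int]:
    """Deterministic taxon addition order: most mutually distant taxa first.

    Starts from the pair with the largest Hamming distance and repeatedly
    appends the taxon with the largest total distance to those already
    chosen; ties break on the taxon label.  Front-loading divergent taxa
    makes partial-tree lengths grow early, which tightens the pruning
    bound; the set of most-parsimonious trees is independent of the order.
    """
    n = len(taxa)
    D = (states[:, None, :] != states[None, :, :]).sum(axis=2)
    pairs = [(int(D[i, j]), i, j) for i in range(n) for j in range(i + 1, n)]
    dmax = max(p[0] for p in pairs)
    # among max-distance pairs prefer the lexicographically smallest labels
    _, i0, j0 = min((p for p in pairs if p[0] == dmax),
                    key=lambda p: (taxa[p[1]], taxa[p[2]]))
    chosen = [i0, j0]
    rest = [i for i in range(n) if i not in chosen]
    while rest:
        best = min(rest, key=lambda i: (-int(D[i, chosen].sum()), taxa[i]))
        chosen.append(best)
        rest.remove(best)
    return chosen


def branch_and_bound(matrix: BinaryTaxonMatrix, *, prune: bool = True,
                     max_trees: Optional[int] = None) -> TreeSet:
    """All most-parsimonious unrooted trees by exact branch and bound.

    The taxon addition order is deterministic (a max-distance heuristic
    with label tie-breaks, see :func:`_addition_order`) and the initial
    upper bound comes from a greedy addition tree, so reruns are
    bit-identical.  With ``prune=False`` this degrades to exhaustive
    enumeration and must give the identical result — that equivalence is
    part of the test surface.  ``max_trees`` guards against degenerate
    matrices whose tie structure yields astronomically many equally short
    trees; exceeding it raises instead of silently truncating.
    """
    if len(matrix.taxa) < 3:
        raise ValidationError("parsimony search needs ≥3 taxa")
    order = _addition_order(matrix.states, matrix.taxa)
    labels = [matrix.taxa[i] for i in order]
    search = _Search(matrix.states[order], prune=prune, max_trees=max_trees)
    nested, score = search.run()
    trees = [_nested_to_tree(x, labels) for x in nested]
    return TreeSet(trees=trees, score=score)


def mp_consensus(matrix: BinaryTaxonMatrix) -> tuple[Tree, int, int]:
    """Strict consensus of all most-parsimonious trees, without storing them.

    Streams the exact branch-and-bound enumeration through a running
    split-set intersection, so matrices whose tie structure yields huge
    numbers of equally short trees (e.g. duplicated taxon rows) remain
    tractable.  Returns (consensus tree, parsimony score, number of MP
    trees visited).  Identical to ``strict_consensus(branch_and_bound(m))``
    whenever the latter is feasible.
    """
    if len(matrix.taxa) < 3:
        raise ValidationError("parsimony search needs ≥3 taxa")
    order = _addition_order(matrix.states, matrix.taxa)
    labels = [matrix.taxa[i] for i in order]
    search = _Search(matrix.states[order], prune=True)
    search.run(collect="splits")
    masks = search.split_intersection or set()
    leaves = frozenset(labels)
    clades = [
        frozenset(labels[i] for i in range(len(labels)) if m >> i & 1)
        for m in masks
    ]
    root = _build_from_clades(leaves, clades)
    return Tree(root, rooted=False), int(search.best), search.n_opt


# ---------------------------------------------------------------------------
# consensus and rooting


def _build_from_clades(leaves: frozenset, clades: Iterable[frozenset],
                       heights: Optional[dict] = None) -> TreeNode:
    """Build a tree node from a laminar family of proper subsets of ``leaves``."""
    fam = sorted({frozenset(c) for c in clades if 1 < len(c) < len(leaves)},
                 key=lambda s: (len(s), sorted(s)))
    root = TreeNode()
    nodes: list[tuple[frozenset, TreeNode]] = []
    for s in fam:
        nodes.append((s, TreeNode(height=None if heights is None else heights.get(s))))
    # parent of each set = smallest strict superset (or root)
    children_of: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
    root_children: list[int] = []
    for i, (s, _) in enumerate(nodes):
        parent = None
        for j in range(i + 1, len(nodes)):
            t = nodes[j][0]
            if s < t:
                parent = j
                break
        if parent is None:
            root_children.append(i)
        else:
            children_of[parent].append(i)
    # attach leaves to their smallest containing set
    leaf_parent: dict[str, Optional[int]] = {}
    for leaf in leaves:
        parent = None
        for j, (t, _) in enumerate(nodes):
            if leaf in t:
                parent = j
                break
        leaf_parent[leaf] = parent
    for i, (_, node) in enumerate(nodes):
        node.children = [nodes[j][1] for j in children_of[i]]
    for leaf in sorted(leaves):
        n = TreeNode(label=leaf, height=0.0 if heights is not None else None)
        p = leaf_parent[leaf]
        (nodes[p][1].children if p is not None else root.children).append(n)
    root.children = [nodes[i][1] for i in root_children] + root.children
    return root


def strict_consensus(trees: TreeSet | Sequence[Tree]) -> Tree:
    """Unrooted tree containing exactly the splits present in every input tree."""
    members = trees.trees if isinstance(trees, TreeSet) else list(trees)
    if not members:
        raise ValidationError("strict consensus of an empty tree set")
    leaves = members[0].leaves
    for t in members[1:]:
        if t.leaves != leaves:
            raise ValidationError("consensus requires a shared leaf set")
    common = members[0].splits()
    for t in members[1:]:
        common &= t.splits()
    anchor = min(leaves)
    # canonical splits exclude the anchor → they form a laminar family
    root = _build_from_clades(leaves, common)
    return Tree(root, rooted=False)


def root_between(tree: Tree, clade_a: Iterable[str], clade_b: Iterable[str]) -> Tree:
    """Root a tree on the edge separating two named clades.

    Taxa outside both clades (e.g. a lineage of unclear affinity) stay on
    whichever side of the root they attach to in the unrooted tree.  When
    more than one edge separates the clades — the stray taxa sit on the
    path between them — the edge adjacent to clade A's side is chosen, so
    the extras group with clade B; if no edge separates them the error
    lists the closest candidates.
    """
    A = frozenset(clade_a)
    B = frozenset(clade_b)
    leaves = tree.leaves
    if not A or not B or not A.issubset(leaves) or not B.issubset(leaves):
        raise ValidationError("clades must be non-empty subsets of the leaf set")
    if A & B:
        raise ValidationError("clades overlap")

    # all edge sides (subtree leafsets of every non-root node, plus their complements)
    sides = set()

    def walk(n: TreeNode) -> frozenset:
        if n.is_leaf:
            ls = frozenset([n.label])
        else:
            ls = frozenset().union(*(walk(c) for c in n.children))
        if n is not tree.root and 0 < len(ls) < len(leaves):
            sides.add(ls)
            sides.add(leaves - ls)
        return ls

    walk(tree.root)
    candidates = sorted(
        (s for s in sides if A <= s and not (B & s)),
        key=lambda s: (len(s), sorted(s)),
    )
    if not candidates:
        raise ValidationError(
            f"no edge separates {sorted(A)} from {sorted(B)}; "
            f"edge sides containing clade A: {[sorted(s) for s in sides if A <= s][:5]}"
        )
    S = candidates[0]
    comp = leaves - S

    splits = tree.splits()
    clades = {S, comp}
    for X in splits:
        Xc = leaves - X
        for side in (X, Xc):
            if side <= S or side <= comp:
                clades.add(side)
                break
    root = _build_from_clades(leaves, clades)
    return Tree(root, rooted=True)
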