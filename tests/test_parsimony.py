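import itertools

import numpy as np
import pytest

from clonodiverge.data_io import BinaryTaxonMatrix, Tree, TreeNode, ValidationError
from clonodiverge.parsimony import (
    branch_and_bound,
    fitch_score,
    mp_consensus,
    root_between,
    strict_consensus,
)

# ---------------------------------------------------------------------------
# independent topology enumeration (nested tuples), used as the oracle


def all_topologies(labels):
    """Every unrooted binary topology on the labels, built independently."""
    if len(labels) == 3:
        yield (labels[0], labels[1], labels[2])
        return
    *rest, last = labels
    for topo in all_topologies(rest):
        for path in _edges(topo):
            yield _insert(topo, path, last)


def _edges(topo):
    out = []

    def walk(node, path):
        out.append(path)
        if isinstance(node, tuple) and len(node) == 2:
            walk(node[0], path + (0,))
            walk(node[1], path + (1,))

    for i, child in enumerate(topo):
        walk(child, (i,))
    return out


def _insert(topo, path, leaf):
    def rec(node, p):
        if not p:
            return (node, leaf)
        return tuple(rec(c, p[1:]) if j == p[0] else c for j, c in enumerate(node))

    return rec(topo, path)


def to_tree(topo):
    def build(x):
        if isinstance(x, str):
            return TreeNode(label=x)
        return TreeNode(children=[build(c) for c in x])

    return Tree(TreeNode(children=[build(c) for c in topo]), rooted=False)


def brute_force_length(topo, columns):
    """Minimum changes by enumerating every internal-node state assignment."""

    def shape(x):
        if isinstance(x, str):
            return x
        return tuple(shape(c) for c in x)

    internals = []

    def collect(node):
        if isinstance(node, tuple):
            internals.append(node)
            for c in node:
                collect(c)

    root = topo
    collect(root)
    total = 0
    for col in columns:
        best = np.inf
        for assign in itertools.product([0, 1], repeat=len(internals)):
            states = dict(zip(map(id, internals), assign))

            def state(node):
                return col[node] if isinstance(node, str) else states[id(node)]

            changes = 0

            def walk(node):
                nonlocal changes
                if isinstance(node, tuple):
                    for c in node:
                        changes += state(c) != state(node)
                        walk(c)

            walk(root)
            best = min(best, changes)
        total += best
    return total


def random_matrix(seed, n_taxa, n_char):
    states = np.random.default_rng(seed).integers(0, 2, size=(n_taxa, n_char))
    return BinaryTaxonMatrix(taxa=[f"T{i}" for i in range(n_taxa)],
                             characters=[f"c{j}" for j in range(n_char)],
                             states=states)


# ---------------------------------------------------------------------------


class TestFitchScore:
    def test_single_synapomorphy_costs_one(self):
        m = BinaryTaxonMatrix(taxa=list("ABCD"), characters=["c"],
                              states=np.array([[0], [0], [1], [1]]))
        t = Tree.from_newick("((A,B),(C,D));")
        assert fitch_score(t, m) == 1

    def test_constant_character_costs_nothing(self):
        m = BinaryTaxonMatrix(taxa=list("ABCD"), characters=["c", "k"],
                              states=np.array([[0, 1], [0, 1], [1, 1], [1, 1]]))
        t = Tree.from_newick("((A,C),(B,D));")
        assert fitch_score(t, m) == 2  # the constant column adds 0

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_bruteforce_ancestral_enumeration(self, seed):
        labels = [f"T{i}" for i in range(6)]
        m = random_matrix(seed, 6, 6)
        col_maps = [{t: int(m.states[i, j]) for i, t in enumerate(labels)}
                    for j in range(6)]
        rng = np.random.default_rng(seed + 100)
        topos = list(all_topologies(labels))
        for topo in rng.choice(len(topos), size=8, replace=False):
            topo = topos[int(topo)]
            assert fitch_score(to_tree(topo), m) == brute_force_length(topo, col_maps)

    def test_invariant_to_rooting_and_leaf_order(self):
        m = random_matrix(3, 5, 6)
        a = Tree.from_newick("((T0,T1),(T2,T3),T4);")
        b = Tree.from_newick("((T3,T2),((T1,T0),T4));")
        assert a.splits() == b.splits()
        assert fitch_score(a, m) == fitch_score(b, m)

    def test_duplicated_character_doubles_its_contribution(self):
        m1 = random_matrix(11, 6, 1)
        m2 = BinaryTaxonMatrix(taxa=m1.taxa, characters=["c", "c2"],
                               states=np.hstack([m1.states, m1.states]))
        t = to_tree(next(all_topologies(m1.taxa)))
        assert fitch_score(t, m2) == 2 * fitch_score(t, m1)

    def test_leaf_mismatch_is_an_error(self):
        m = random_matrix(0, 4, 3)
        with pytest.raises(ValidationError):
            fitch_score(Tree.from_newick("(A,B,C);"), m)


class TestBranchAndBound:
    def test_three_taxa_single_topology(self):
        m = random_matrix(1, 3, 4)
        ts = branch_and_bound(m)
        assert len(ts) == 1
        assert ts.trees[0].leaves == frozenset(m.taxa)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_enumeration_on_seven_taxa(self, seed):
        m = random_matrix(seed, 7, 8)
        topos = list(all_topologies(m.taxa))
        assert len(topos) == 945
        scores = [fitch_score(to_tree(t), m) for t in topos]
        best = min(scores)
        expected = {to_tree(t).splits() for t, s in zip(topos, scores) if s == best}
        ts = branch_and_bound(m)
        assert ts.score == best
        assert {t.splits() for t in ts.trees} == expected
        assert len(ts.trees) == len(expected)  # no duplicate topologies

    def test_prune_equals_no_prune(self):
        m = random_matrix(42, 6, 6)
        a = branch_and_bound(m)
        b = branch_and_bound(m, prune=False)
        assert a.score == b.score
        assert {t.splits() for t in a.trees} == {t.splits() for t in b.trees}

    def test_all_members_share_the_optimal_score(self):
        m = random_matrix(13, 7, 6)
        ts = branch_and_bound(m)
        assert all(fitch_score(t, m) == ts.score for t in ts.trees)

    def test_score_not_above_any_adversarial_tree(self, rng):
        m = random_matrix(7, 7, 9)
        ts = branch_and_bound(m)
        for topo in list(all_topologies(m.taxa))[:: 97]:
            assert ts.score <= fitch_score(to_tree(topo), m)

    def test_max_trees_guard_raises(self):
        states = np.zeros((8, 4), dtype=int)
        states[4:] = 1  # fully tied: many equally short trees
        m = BinaryTaxonMatrix(taxa=[f"T{i}" for i in range(8)],
                              characters=list("abcd"), states=states)
        with pytest.raises(ValidationError, match="most-parsimonious"):
            branch_and_bound(m, max_trees=3)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValidationError):
            branch_and_bound(random_matrix(0, 2, 3))

    @pytest.mark.parametrize("seed", range(3))
    def test_streaming_consensus_matches_materialized(self, seed):
        m = random_matrix(seed + 50, 8, 7)
        ts = branch_and_bound(m)
        cons, score, n = mp_consensus(m)
        assert score == ts.score and n == len(ts)
        assert cons.splits() == strict_consensus(ts).splits()


class TestStrictConsensus:
    def test_single_tree_is_its_own_consensus(self):
        t = Tree.from_newick("((A,B),(C,D),(E,F));")
        c = strict_consensus([t])
        assert c.splits() == t.splits()

    def test_conflicting_quartets_give_star(self):
        a = Tree.from_newick("((A,B),(C,D));")
        b = Tree.from_newick("((A,C),(B,D));")
        c = strict_consensus([a, b])
        assert c.splits() == frozenset()

    @pytest.mark.parametrize("seed", range(5))
    def test_split_set_is_intersection(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"T{i}" for i in range(7)]
        topos = list(all_topologies(labels))
        pair = [to_tree(topos[int(i)]) for i in rng.choice(len(topos), 2)]
        c = strict_consensus(pair)
        assert c.splits() == pair[0].splits() & pair[1].splits()

    def test_consensus_compatible_with_every_member(self):
        m = random_matrix(5, 7, 5)
        ts = branch_and_bound(m)
        c = strict_consensus(ts)
        for t in ts.trees:
            assert c.splits() <= t.splits()

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValidationError):
            strict_consensus([])


class TestRootBetween:
    def test_quartet_rooted_between_pairs(self):
        t = Tree.from_newick("((A,B),(C,D));")
        r = root_between(t, ["A", "B"], ["C", "D"])
        assert r.rooted
        assert frozenset("AB") in r.clades() and frozenset("CD") in r.clades()

    def test_extra_taxon_stays_on_its_attachment_side(self):
        # SH-like stray leaf attached inside the A side
        t = Tree.from_newick("(((A1,SH),A2),(B1,B2),B3);")
        r = root_between(t, ["A1", "A2"], ["B1", "B2", "B3"])
        assert frozenset({"A1", "A2", "SH"}) in r.clades() | {r.root.leafset()}
        assert frozenset({"B1", "B2", "B3"}) in r.clades()

    def test_rooting_preserves_unrooted_splits(self):
        t = Tree.from_newick("((A,B),(C,(D,E)),F);")
        r = root_between(t, ["A", "B"], ["D", "E"])
        assert r.splits() == t.splits()

    def test_no_separating_edge_is_an_error(self):
        t = Tree.from_newick("((A,C),(B,D));")
        with pytest.raises(ValidationError, match="no edge separates"):
            root_between(t, ["A", "B"], ["C", "D"])

    def test_overlapping_clades_rejected(self):
        t = Tree.from_newick("((A,B),(C,D));")
        with pytest.raises(ValidationError):
            root_between(t, ["A", "B"], ["B", "C"])
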