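"""Clade machinery: parsing, clade sets, concordance, consensus, rooting."""

import itertools

import numpy as np
import pytest

from phyloconcord.trees import (
    LeafSetMismatchError,
    NewickParseError,
    clade_set,
    concordance,
    leaf_labels,
    majority_rule_extended_consensus,
    parse_newick,
    root_tree,
    tree_from_clades,
    write_newick,
)

from conftest import caterpillar_newick, random_binary_newick, swapped_caterpillar_labels


# --- independent oracle: nested-tuple newick reader and clade enumerator ---

def _read_tuple(s):
    """Minimal recursive-descent newick-to-nested-tuple reader (no dendropy)."""
    s = s.strip().rstrip(";")
    pos = [0]

    def parse():
        if s[pos[0]] == "(":
            pos[0] += 1
            children = [parse()]
            while s[pos[0]] == ",":
                pos[0] += 1
                children.append(parse())
            assert s[pos[0]] == ")"
            pos[0] += 1
            return tuple(children)
        start = pos[0]
        while pos[0] < len(s) and s[pos[0]] not in ",()":
            pos[0] += 1
        return s[start:pos[0]]

    return parse()


def _tuple_leaves(t):
    if isinstance(t, str):
        return frozenset([t])
    return frozenset().union(*(_tuple_leaves(c) for c in t))


def _tuple_clades(t, n_total):
    """All non-trivial clades of a nested-tuple tree, brute force."""
    out = set()

    def walk(node, is_root):
        if isinstance(node, str):
            return frozenset([node])
        ls = frozenset().union(*(walk(c, False) for c in node))
        if not is_root and 2 <= len(ls) < n_total:
            out.add(ls)
        return ls

    walk(t, True)
    return out


def _all_rooted_binary(labels):
    """Enumerate all (2n-3)!! rooted binary topologies as nested tuples."""
    if len(labels) == 1:
        return [labels[0]]
    first, rest = labels[0], labels[1:]
    out = []
    for t in _all_rooted_binary(rest):
        for spot in _insertion_points(t):
            out.append(_insert(t, spot, first))
    return out


def _insertion_points(t):
    yield ()  # above the root
    if isinstance(t, tuple):
        for i, c in enumerate(t):
            for sub in _insertion_points(c):
                yield (i,) + sub


def _insert(t, spot, label):
    if spot == ():
        return (t, label)
    i = spot[0]
    return tuple(_insert(c, spot[1:], label) if j == i else c
                 for j, c in enumerate(t))


# --- parsing ---

def test_parse_preserves_topology_and_polytomies():
    t = parse_newick("(A,(B,C));")
    assert clade_set_with_small(t) == {frozenset("BC")}
    star = parse_newick("(A,B,C,D);")
    assert clade_set(star) == frozenset()
    roundtrip = parse_newick(write_newick(parse_newick("((A,B),(C,(D,E)));")))
    assert clade_set(roundtrip) == {frozenset("AB"), frozenset("CDE"),
                                    frozenset("DE")}


def clade_set_with_small(t):
    # helper for <4-leaf trees in parsing tests only
    n = len(leaf_labels(t))
    out = set()
    for node in t.preorder_internal_node_iter(exclude_seed_node=True):
        ls = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(ls) < n:
            out.add(ls)
    return out


@pytest.mark.parametrize("bad", ["(A,(B,C)", "(A,B));", "((A,B),(A,C));"])
def test_parse_rejects_malformed_or_duplicate(bad):
    with pytest.raises(NewickParseError):
        parse_newick(bad)


def test_parse_error_names_offset():
    with pytest.raises(NewickParseError, match="offset"):
        parse_newick("(A,B))C;")


# --- clade sets ---

def test_binary_rooted_clade_count_is_n_minus_2(rng):
    for n in (4, 5, 7, 10):
        labels = [f"t{i}" for i in range(n)]
        t = parse_newick(random_binary_newick(labels, rng))
        assert len(clade_set(t)) == n - 2


def test_clade_set_requires_four_leaves():
    with pytest.raises(ValueError):
        clade_set(parse_newick("(A,(B,C));"))


def test_clade_set_matches_bruteforce_oracle(rng):
    for n in (5, 6, 7):
        labels = [f"t{i}" for i in range(n)]
        for _ in range(25):
            nwk = random_binary_newick(labels, rng)
            ours = clade_set(parse_newick(nwk))
            oracle = _tuple_clades(_read_tuple(nwk), n)
            assert ours == oracle


# --- concordance ---

def test_identical_trees_fully_concordant(rng):
    for n in (4, 9, 17):
        t = parse_newick(random_binary_newick([f"x{i}" for i in range(n)], rng))
        r = concordance(t, t)
        assert r.concordance == 1.0
        assert r.shared == r.reference_clades == n - 2


def test_one_nni_on_17_leaves_gives_93_3_percent():
    """A single rearranged bipartition among 17 taxa leaves 14/15 clades."""
    labels = [f"L{i:02d}" for i in range(17)]
    ref = parse_newick(caterpillar_newick(labels))
    alt = parse_newick(caterpillar_newick(swapped_caterpillar_labels(labels, 1)))
    r = concordance(ref, alt)
    assert (r.reference_clades, r.shared) == (15, 14)
    assert round(100 * r.concordance, 1) == 93.3


@pytest.mark.parametrize("n,d,expected", [(47, 2, 95.6), (82, 11, 86.3)])
def test_disjoint_nni_concordance_matches_clade_arithmetic(n, d, expected):
    labels = [f"L{i:03d}" for i in range(n)]
    ref = parse_newick(caterpillar_newick(labels))
    alt = parse_newick(caterpillar_newick(swapped_caterpillar_labels(labels, d)))
    r = concordance(ref, alt)
    assert r.reference_clades == n - 2
    assert r.shared == n - 2 - d
    # half-up rounding to one decimal, the printing convention for percentages
    assert np.floor(r.as_percent() * 10 + 0.5) / 10 == expected


def test_concordance_is_asymmetric_with_polytomy_reference():
    ref = parse_newick("((A,B),C,(D,E));")  # polytomy: only 2 clades
    other = parse_newick("(((A,B),C),(D,E));")
    r = concordance(ref, other)
    assert r.reference_clades == 2
    assert r.concordance == 1.0
    r2 = concordance(other, ref)
    assert r2.reference_clades == 3
    assert r2.shared == 2


def test_concordance_leafset_mismatch_lists_difference():
    a = parse_newick("((A,B),(C,D));")
    b = parse_newick("((A,B),(C,E));")
    with pytest.raises(LeafSetMismatchError, match="'D', 'E'"):
        concordance(a, b)


def test_concordance_exhaustive_on_small_trees():
    """All rooted binary tree pairs on <= 5 leaves match the brute-force oracle."""
    labels = list("ABCDE")
    tuples = _all_rooted_binary(labels)
    assert len(tuples) == 105  # (2n-3)!!
    newicks = []

    def fmt(t):
        if isinstance(t, str):
            return t
        return "(" + ",".join(fmt(c) for c in t) + ")"

    for t in tuples:
        newicks.append((t, parse_newick(fmt(t) + ";")))
    for (ta, a), (tb, b) in itertools.product(newicks[:35], newicks[::5]):
        ca = _tuple_clades(ta, 5)
        cb = _tuple_clades(tb, 5)
        r = concordance(a, b)
        assert r.reference_clades == len(ca) == 3
        assert r.shared == len(ca & cb)


def test_concordance_random_7_leaf_pairs_match_oracle(rng):
    labels = [f"t{i}" for i in range(7)]
    for _ in range(200):
        na, nb = (random_binary_newick(labels, rng) for _ in range(2))
        r = concordance(parse_newick(na), parse_newick(nb))
        ca = _tuple_clades(_read_tuple(na), 7)
        cb = _tuple_clades(_read_tuple(nb), 7)
        assert (r.reference_clades, r.shared) == (len(ca), len(ca & cb))


# --- consensus ---

def test_consensus_of_identical_trees_is_that_tree(rng):
    t = parse_newick(random_binary_newick([f"s{i}" for i in range(8)], rng))
    cons = majority_rule_extended_consensus([t, t, t])
    assert clade_set(cons) == clade_set(t)


def test_majority_rule_inclusion():
    t1 = parse_newick("(((A,B),C),(D,E));")
    t2 = parse_newick("(((A,B),D),(C,E));")
    t3 = parse_newick("(((A,C),B),(D,E));")
    cons = majority_rule_extended_consensus([t1, t2, t3])
    clades = clade_set(cons)
    assert frozenset("AB") in clades  # 2/3
    assert frozenset("DE") in clades  # 2/3


def test_consensus_greedy_stage_resolves_half_frequency_conflict():
    """Two trees, one conflicting clade each at frequency 0.5: the greedy
    stage must pick a maximal compatible subset per the documented tie-break
    (smaller clade first, then lexicographic)."""
    t1 = parse_newick("(((A,B),C),(D,E));")   # clades AB, ABC, DE
    t2 = parse_newick("(((A,B),D),(C,E));")   # clades AB, ABD, CE
    cons = majority_rule_extended_consensus([t1, t2])
    clades = clade_set(cons)
    assert frozenset("AB") in clades  # frequency 1.0
    # conflicting pairs: {ABC vs ABD} compatible with either of {DE, CE}?
    # ABC conflicts CE... exhaustive check: result must be a maximal
    # pairwise-compatible subset of the candidate clades
    candidates = {frozenset("ABC"), frozenset("ABD"),
                  frozenset("DE"), frozenset("CE")}
    chosen = clades & candidates
    for extra in candidates - chosen:
        compatible = all(
            extra.isdisjoint(c) or extra <= c or c <= extra
            for c in clades
        )
        assert not compatible, f"greedy stage missed addable clade {set(extra)}"
    # deterministic tie-break: smaller clades first, lexicographic within a
    # size class -> CE enters before DE, which then conflicts; ABD is the
    # 3-clade still compatible with {AB, CE}
    assert chosen == {frozenset("CE"), frozenset("ABD")}


def test_consensus_majority_rule_on_random_triples(rng):
    labels = [f"g{i}" for i in range(7)]
    for _ in range(60):
        trees = [parse_newick(random_binary_newick(labels, rng))
                 for _ in range(3)]
        cons = majority_rule_extended_consensus(trees)
        counts = {}
        for t in trees:
            for c in clade_set(t):
                counts[c] = counts.get(c, 0) + 1
        cons_clades = clade_set(cons)
        for c, k in counts.items():
            if k >= 2:
                assert c in cons_clades


# --- rooting ---

def _unrooted_splits(tree):
    labels = frozenset(leaf_labels(tree))
    out = set()
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        ls = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(ls) <= len(labels) - 2:
            out.add(frozenset({ls, labels - ls}))
    return out


def test_outgroup_rooting_places_outgroup_at_root():
    t = parse_newick("((A:1,B:1):1,(C:1,(D:1,O:1):1):1);")
    rooted = root_tree(t, method="outgroup", outgroup=["O"])
    root_children = rooted.seed_node.child_nodes()
    subtended = [frozenset(lf.taxon.label for lf in c.leaf_iter())
                 for c in root_children]
    assert frozenset(["O"]) in subtended


def test_rooting_preserves_unrooted_split_set(rng):
    labels = [f"u{i}" for i in range(8)]
    t = parse_newick(random_binary_newick(labels, rng))
    for e in t.preorder_edge_iter():
        e.length = float(rng.uniform(0.2, 2.0))
    before = _unrooted_splits(t)
    mid = root_tree(t, method="midpoint")
    assert _unrooted_splits(mid) == before
    out = root_tree(t, method="outgroup", outgroup=[labels[0]])
    assert _unrooted_splits(out) == before


def test_outgroup_rooting_missing_label_errors():
    t = parse_newick("((A,B),(C,D));")
    with pytest.raises(ValueError, match="ZZ"):
        root_tree(t, method="outgroup", outgroup=["ZZ"])


def test_tree_from_clades_rejects_incompatible():
    with pytest.raises(ValueError, match="incompatible"):
        tree_from_clades("ABCD", [frozenset("AB"), frozenset("BC")])
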