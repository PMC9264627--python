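"""Rooted-tree machinery: Newick I/O, clade sets, concordance, consensus, rooting.

Trees are held as :class:`dendropy.Tree` objects and always interpreted as
rooted at their seed node.  The central statistic is *concordance*: the
proportion of the reference tree's non-trivial clades (leaf sets subtended by
internal nodes, excluding single leaves and the full taxon set) that are also
present in a comparison tree.  For two fully binary trees on the same n taxa
this equals 1 minus the rooted Robinson-Foulds distance divided by n - 2; the
reference tree always supplies the denominator, so the statistic is asymmetric
and remains well defined when the reference contains polytomies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "NewickParseError",
    "LeafSetMismatchError",
    "ConcordanceResult",
    "parse_newick",
    "write_newick",
    "leaf_labels",
    "clade_set",
    "concordance",
    "majority_rule_extended_consensus",
    "root_tree",
    "tree_from_clades",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or violates label rules."""


class LeafSetMismatchError(ValueError):
    """Raised when two trees that must share a leaf set do not."""


@dataclass(frozen=True)
class ConcordanceResult:
    """Outcome of a reference-denominated clade comparison.

    Attributes
    ----------
    reference_clades : int
        Number of non-trivial clades in the reference tree (the denominator).
    shared : int
        Number of those clades also present in the comparison tree.
    concordance : float
        ``shared / reference_clades``, in [0, 1].
    """

    reference_clades: int
    shared: int
    concordance: float

    def as_percent(self) -> float:
        return 100.0 * self.concordance


def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character offset {offset}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(': {depth} unclosed at end of string"
        )


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick string into a rooted tree.

    Polytomies are preserved; internal node labels (e.g. bootstrap supports)
    are kept as node labels, not taxa.  Raises :class:`NewickParseError` for
    malformed input (naming a character offset for unbalanced parentheses) or
    duplicate/empty leaf labels.
    """
    _check_parentheses(text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    labels = leaf_labels(tree)
    if any(not lab for lab in labels):
        raise NewickParseError("empty leaf label")
    dupes = [lab for lab, k in Counter(labels).items() if k > 1]
    if dupes:
        raise NewickParseError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree, *, branch_lengths: bool = True) -> str:
    """Serialize a tree to a one-line Newick string (trailing ``;`` included)."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_edge_lengths=not branch_lengths,
    )
    return s.strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _node_leafsets(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf sets of all internal nodes below the root, in preorder."""
    out = []
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


def _clades(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    n = len(leaf_labels(tree))
    return frozenset(
        ls for ls in _node_leafsets(tree) if 2 <= len(ls) < n
    )


def clade_set(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """All non-trivial clades of a rooted tree (size >= 2, excluding the root).

    Requires >= 4 leaves; with fewer there is no non-trivial comparison to
    make.  For a fully binary rooted tree the result has exactly n - 2
    members; polytomies yield fewer.
    """
    labels = leaf_labels(tree)
    if len(labels) < 4:
        raise ValueError(
            f"clade_set requires >= 4 leaves, got {len(labels)}"
        )
    return _clades(tree)


def _require_same_leaves(a: dendropy.Tree, b: dendropy.Tree) -> None:
    la, lb = set(leaf_labels(a)), set(leaf_labels(b))
    if la != lb:
        diff = sorted(la.symmetric_difference(lb))
        raise LeafSetMismatchError(
            f"leaf sets differ; symmetric difference: {diff}"
        )


def concordance(reference: dendropy.Tree, other: dendropy.Tree) -> ConcordanceResult:
    """Proportion of the reference tree's non-trivial clades found in ``other``.

    Asymmetric: the reference supplies the denominator.  Both trees must share
    an identical leaf set and the reference must have >= 4 leaves and at least
    one non-trivial clade (i.e. not be a star tree).
    """
    _require_same_leaves(reference, other)
    ref = clade_set(reference)
    if not ref:
        raise ValueError("reference tree is a star tree: no non-trivial clades")
    oth = _clades(other)
    shared = len(ref & oth)
    return ConcordanceResult(
        reference_clades=len(ref),
        shared=shared,
        concordance=shared / len(ref),
    )


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a.isdisjoint(b) or a <= b or b <= a


def tree_from_clades(
    leaves: Iterable[str], clades: Iterable[frozenset[str]]
) -> dendropy.Tree:
    """Build a rooted tree from a pairwise-compatible set of clades."""
    leaves = sorted(set(leaves))
    clades = sorted(set(map(frozenset, clades)), key=lambda c: (len(c), sorted(c)))
    for i, a in enumerate(clades):
        for b in clades[i + 1:]:
            if not _compatible(a, b):
                raise ValueError(f"incompatible clades: {sorted(a)} vs {sorted(b)}")

    def emit(members: frozenset, inside: list[frozenset]) -> str:
        maximal = [
            c for c in inside
            if not any(c < d for d in inside)
        ]
        covered: set[str] = set()
        parts = []
        for c in sorted(maximal, key=lambda c: sorted(c)):
            sub = [d for d in inside if d < c]
            parts.append(emit(c, sub))
            covered |= c
        for leaf in sorted(members - covered):
            parts.append(leaf)
        return "(" + ",".join(parts) + ")"

    root = frozenset(leaves)
    inner = [c for c in clades if c < root]
    return parse_newick(emit(root, inner) + ";")


def majority_rule_extended_consensus(
    trees: Sequence[dendropy.Tree],
) -> dendropy.Tree:
    """Majority-rule extended consensus of rooted trees on one leaf set.

    Every clade appearing in more than half of the input trees is included;
    remaining clades are then added greedily, in order of decreasing
    frequency, whenever compatible with the clades accepted so far.  Ties in
    frequency are broken by smaller clade first, then by the lexicographic
    order of the sorted leaf list — the same every run.
    """
    if not trees:
        raise ValueError("need at least one tree")
    for t in trees[1:]:
        _require_same_leaves(trees[0], t)
    leaves = sorted(leaf_labels(trees[0]))
    n = len(leaves)
    counts: Counter[frozenset[str]] = Counter()
    for t in trees:
        for ls in set(_clades(t) if n >= 4 else
                      frozenset(s for s in _node_leafsets(t) if 2 <= len(s) < n)):
            counts[ls] += 1
    k = len(trees)
    accepted: list[frozenset[str]] = []
    majority = [c for c, m in counts.items() if m / k > 0.5]
    accepted.extend(majority)  # majority clades are mutually compatible
    rest = sorted(
        (c for c, m in counts.items() if m / k <= 0.5),
        key=lambda c: (-counts[c], len(c), sorted(c)),
    )
    for c in rest:
        if all(_compatible(c, a) for a in accepted):
            accepted.append(c)
    return tree_from_clades(leaves, accepted)


def _unrooted_splits(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    labels = frozenset(leaf_labels(tree))
    out = set()
    for ls in _node_leafsets(tree):
        if 2 <= len(ls) <= len(labels) - 2:
            out.add(frozenset({ls, labels - ls}))
    return out


def root_tree(
    tree: dendropy.Tree,
    method: str = "midpoint",
    outgroup: Iterable[str] | None = None,
) -> dendropy.Tree:
    """Return a rooted copy of ``tree``.

    ``method="midpoint"`` roots at the midpoint of the longest leaf-to-leaf
    path (requires branch lengths).  ``method="outgroup"`` roots on the edge
    above the given outgroup (single leaf or the MRCA of several).  Either way
    the unrooted split set is unchanged.
    """
    t = parse_newick(write_newick(tree))
    if method == "midpoint":
        if any(e.length is None for e in t.preorder_edge_iter()
               if e.head_node is not t.seed_node):
            raise ValueError("midpoint rooting requires branch lengths")
        total = sum(e.length or 0.0 for e in t.preorder_edge_iter())
        if total > 0.0:
            t.reroot_at_midpoint(update_bipartitions=False)
        # a zero-length tree has no defined midpoint; keep the root as-is
    elif method == "outgroup":
        if not outgroup:
            raise ValueError("outgroup labels required for outgroup rooting")
        og = sorted(set(outgroup))
        present = set(leaf_labels(t))
        missing = [x for x in og if x not in present]
        if missing:
            raise ValueError(f"outgroup labels not in tree: {missing}")
        if len(og) == 1:
            node = t.find_node_with_taxon_label(og[0])
        else:
            node = t.mrca(taxon_labels=og)
            if node is t.seed_node:
                # outgroup spans the root; root on the ingroup side instead
                node = t.mrca(taxon_labels=sorted(present - set(og)))
        edge = node.edge
        if edge.length is not None:
            t.reroot_at_edge(edge, length1=edge.length / 2.0,
                             length2=edge.length / 2.0,
                             update_bipartitions=False)
        else:
            t.reroot_at_edge(edge, update_bipartitions=False)
    else:
        raise ValueError(f"unknown rooting method: {method!r}")
    t.suppress_unifurcations()
    return t
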