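"""Built-in distance-based tree estimation: JC distances, NJ, bootstrap.

The estimator contract used throughout the package is simply a callable
``estimator(alignment) -> rooted dendropy.Tree``.  The built-in implementation
is neighbor joining on Jukes-Cantor-corrected distances followed by midpoint
rooting; any external program can be substituted behind the same callable.

Determinism: labels are sorted lexicographically before NJ, and ties in the
Q matrix resolve to the lowest (row, column) index pair, so the same distance
matrix always yields the same tree regardless of input order.
"""

from __future__ import annotations

from typing import Callable, Iterable

import dendropy
import numpy as np
import pandas as pd

from .alignment import Alignment
from .trees import parse_newick, root_tree, clade_set, leaf_labels

__all__ = [
    "JC_MAX_DISTANCE",
    "jc_distance_matrix",
    "nj_tree",
    "nj_estimator",
    "bootstrap_supports",
]

#: Distance assigned when the mismatch proportion reaches the Jukes-Cantor
#: singularity p >= 0.75 (saturation); keeps matrices finite.
JC_MAX_DISTANCE = 5.0

Estimator = Callable[[Alignment], dendropy.Tree]

_ACGT = np.array(["A", "C", "G", "T"])


def jc_distance_matrix(aln: Alignment) -> pd.DataFrame:
    """Pairwise Jukes-Cantor distances, d = -(3/4) ln(1 - (4/3) p.

    p is the mismatch proportion over columns where both sequences carry a
    called base (A/C/G/T); gap/N columns are excluded pairwise.  Saturated
    pairs (p >= 0.75) receive :data:`JC_MAX_DISTANCE`.  A pair with zero
    shared called columns is an error.
    """
    if aln.n_taxa < 2:
        raise ValueError("need >= 2 sequences")
    valid = np.isin(aln.data, _ACGT)
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            shared = int(both.sum())
            if shared == 0:
                raise ValueError(
                    f"no shared ungapped columns between "
                    f"{aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            p = float((aln.data[i, both] != aln.data[j, both]).sum()) / shared
            if p >= 0.75:
                dist = JC_MAX_DISTANCE
            else:
                dist = max(0.0, float(-0.75 * np.log(1.0 - (4.0 / 3.0) * p)))
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=aln.ids, columns=aln.ids)


def nj_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted topology, rooted at a trifurcation).

    Input must be a symmetric, zero-diagonal, nonnegative labelled matrix
    with >= 3 taxa.  Negative branch-length estimates are clamped to zero.
    """
    labels = list(dist.index)
    if list(dist.columns) != labels:
        raise ValueError("distance matrix index and columns differ")
    if len(labels) < 3:
        raise ValueError("need >= 3 taxa")
    m = dist.to_numpy(dtype=float)
    if not np.allclose(m, m.T):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(m) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(m < 0):
        raise ValueError("distances must be nonnegative")

    order = np.argsort(labels)
    labels = [labels[i] for i in order]
    m = m[np.ix_(order, order)].copy()
    nodes = [lab for lab in labels]  # newick fragments

    def fmt(x: float) -> str:
        return format(max(x, 0.0) + 0.0, ".10g")  # +0.0 normalizes -0.0

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = m.sum(axis=1)
        q = (r - 2) * m - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin -> lowest (i, j) with i < j on ties
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * m[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = m[i, j] - li
        merged = f"({nodes[i]}:{fmt(li)},{nodes[j]}:{fmt(lj)})"
        new_d = 0.5 * (m[i] + m[j] - m[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        m2 = np.zeros((r - 1, r - 1))
        m2[1:, 1:] = m[np.ix_(keep, keep)]
        m2[0, 1:] = m2[1:, 0] = new_d[keep]
        m = m2
        nodes = [merged] + [nodes[k] for k in keep]

    d01, d02, d12 = m[0, 1], m[0, 2], m[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    newick = (f"({nodes[0]}:{fmt(l0)},{nodes[1]}:{fmt(l1)},"
              f"{nodes[2]}:{fmt(l2)});")
    return parse_newick(newick)


def nj_estimator(
    rooting: str = "midpoint", outgroup: Iterable[str] | None = None
) -> Estimator:
    """Build the default estimator: JC distances -> NJ -> rooting."""

    def estimate(aln: Alignment) -> dendropy.Tree:
        tree = nj_tree(jc_distance_matrix(aln))
        return root_tree(tree, method=rooting, outgroup=outgroup)

    return estimate


def bootstrap_supports(
    aln: Alignment,
    estimator: Estimator,
    replicates: int,
    seed: int,
) -> dendropy.Tree:
    """Point estimate with internal nodes annotated by bootstrap support (%).

    Columns are resampled with replacement ``replicates`` times (seeded); the
    support of each internal node of the point tree is the percentage of
    replicate trees containing its clade.  Replicates on which the estimator
    fails (e.g. a fully saturated pair) are skipped and excluded from the
    denominator.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    point = estimator(aln)
    rng = np.random.default_rng(seed)
    n = len(leaf_labels(point))
    counts: dict[frozenset, int] = {}
    done = 0
    for _ in range(replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        try:
            rep = estimator(aln.take_columns(cols))
        except ValueError:
            continue
        done += 1
        for c in clade_set(rep):
            counts[c] = counts.get(c, 0) + 1
    if done == 0:
        raise ValueError("every bootstrap replicate failed")
    for node in point.preorder_internal_node_iter(exclude_seed_node=True):
        ls = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(ls) < n:
            support = 100.0 * counts.get(ls, 0) / done
            node.label = format(support, ".4g")
    return point
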