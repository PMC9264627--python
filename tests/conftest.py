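import numpy as np
import pytest

from phyloconcord.estimate import nj_estimator


def random_binary_newick(labels, rng):
    """Random rooted binary tree over labels, by repeated random joining."""
    items = list(labels)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b})")
    return items[0] + ";"


def caterpillar_newick(labels):
    s = f"({labels[0]},{labels[1]})"
    for lab in labels[2:]:
        s = f"({s},{lab})"
    return s + ";"


def swapped_caterpillar_labels(labels, n_swaps):
    """Swap leaf pairs at positions (3,4), (5,6), ... (1-based).

    Each swap removes exactly one prefix clade of the caterpillar and the
    swap positions are disjoint, so n_swaps swaps remove exactly n_swaps
    clades of the reference caterpillar.
    """
    out = list(labels)
    for k in range(n_swaps):
        i = 2 + 2 * k  # 0-based index of position 3, 5, 7, ...
        out[i], out[i + 1] = out[i + 1], out[i]
    return out


@pytest.fixture(scope="session")
def estimator():
    return nj_estimator()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
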