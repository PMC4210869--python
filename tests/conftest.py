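import numpy as np
import pytest
from skbio import TreeNode

from funcphylo.seqdist import Alignment


def random_binary_tree(labels, rng, length_range=(0.05, 0.2)) -> TreeNode:
    """Random rooted binary tree over ``labels`` by sequential joining."""
    nodes = [TreeNode(name=l) for l in labels]
    lo, hi = length_range
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop larger index first
        parent = TreeNode()
        a.length = float(rng.uniform(lo, hi))
        b.length = float(rng.uniform(lo, hi))
        parent.extend([a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def gapped_alignment():
    # one column (index 2) carries a gap and must be dropped entirely
    return Alignment(
        labels=["s1", "s2", "s3"],
        sequences=["ACDEF", "ACEEF", "AC-EY"],
    )
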