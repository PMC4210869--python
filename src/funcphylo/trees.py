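"""Tree building and tree metrics for receptor phylogenetics.

Two kinds of trees are produced:

* a sequence tree from a pairwise distance matrix via Saitou-Nei
  Neighbor-Joining (NJ), with optional bootstrap supports from column
  resampling of the alignment; and
* a ligand-specificity tree from the Euclidean distances between receptor
  activity profiles, via agglomerative hierarchical clustering.

Trees are `skbio.TreeNode` objects throughout, so Newick round-tripping
and patristic (tip-to-tip path length) distances come from scikit-bio.
NJ is implemented here because run-to-run reproducibility requires a
defined tie-break (lexicographically smallest label pair) that generic
implementations do not guarantee; it is cross-checked against independent
implementations in the test suite.
"""

from __future__ import annotations

import io
import itertools
import logging

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .seqdist import Alignment, pairwise_distance

logger = logging.getLogger(__name__)

_LINKAGES = ("single", "complete", "average")


def _check_square(dm: DistanceMatrix) -> None:
    if not np.allclose(dm.data, dm.data.T):
        raise ValueError("distance matrix is not symmetric")


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei Neighbor-Joining tree from a distance matrix.

    At each step the pair (i, j) minimizing
    ``Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)``
    is joined; branch lengths follow the standard formulas and the
    reduced distances are ``d(u, k) = (d(i, k) + d(j, k) - d(i, j)) / 2``.
    Ties in Q are broken by the lexicographically smallest pair of
    subtree labels (each active node is keyed by the smallest tip label
    beneath it), making runs bit-reproducible.  Negative branch lengths
    are clamped to zero; the number of clamped branches is recorded on
    the returned tree as ``negative_branches_clamped``.

    Returns an unrooted tree represented with a trifurcating root.
    NJ is exact on additive matrices: it recovers the generating tree's
    topology and branch lengths.
    """
    _check_square(dm)
    labels = list(dm.ids)
    n0 = len(labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    keys: list[str] = list(labels)  # smallest tip label under each node
    d = dm.data.astype(float).copy()
    clamped = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            logger.debug("clamped negative branch length %g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        # Q matrix; select minimal entry with lexicographic tie-break.
        best = None
        best_q = np.inf
        for i, j in itertools.combinations(range(n), 2):
            q = (n - 2) * d[i, j] - r[i] - r[j]
            key = tuple(sorted((keys[i], keys[j])))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12 and (best is None or key < best[2])
            ):
                best_q = q
                best = (i, j, key)
        i, j, _ = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        vj = d[i, j] - vi
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length = _clamp(vi)
        cj.length = _clamp(vj)
        parent.extend([ci, cj])

        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = dnew[keep]
        d[:-1, -1] = dnew[keep]
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    # Final three nodes: three-point formulas around a trifurcating root.
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = _clamp(0.5 * (dab + dac - dbc))
    b.length = _clamp(0.5 * (dab + dbc - dac))
    c.length = _clamp(0.5 * (dac + dbc - dab))
    root = TreeNode()
    root.extend([a, b, c])
    root.negative_branches_clamped = clamped
    return root


def specificity_tree(dm: DistanceMatrix, linkage: str = "average") -> TreeNode:
    """Ligand-specificity dendrogram by agglomerative clustering.

    Hierarchical clustering (scipy) of the receptor-by-receptor distance
    matrix with the chosen linkage (average by default).  The returned
    rooted tree carries merge heights: each branch length is the height
    difference between a node's merge and its child's.
    """
    _check_square(dm)
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {_LINKAGES}")
    labels = list(dm.ids)
    if len(labels) < 2:
        raise ValueError("specificity tree needs at least 2 taxa")
    Z = hierarchy.linkage(squareform(dm.data, checks=False), method=linkage)
    root_cl, _ = hierarchy.to_tree(Z, rd=True)

    def convert(cl) -> tuple[TreeNode, float]:
        if cl.is_leaf():
            return TreeNode(name=labels[cl.id]), 0.0
        left, hl = convert(cl.left)
        right, hr = convert(cl.right)
        h = cl.dist
        left.length = h - hl
        right.length = h - hr
        node = TreeNode()
        node.height = h
        node.extend([left, right])
        return node, h

    root, _ = convert(root_cl)
    root.length = None
    return root


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (effectively unrooted) tree.

    Each internal edge splits the tips in two; the side not containing
    the globally smallest tip label is the canonical representative, so
    rooted and unrooted encodings of the same topology agree.
    """
    tips = {t.name for t in tree.tips()}
    anchor = min(tips)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = frozenset(tips - side)
        if 2 <= len(side) <= len(tips) - 2:
            parts.add(side)
    return parts


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    tips1 = {t.name for t in t1.tips()}
    tips2 = {t.name for t in t2.tips()}
    if tips1 != tips2:
        raise ValueError(
            f"trees have different leaf sets: {sorted(tips1 ^ tips2)} unshared"
        )
    return len(_bipartitions(t1) ^ _bipartitions(t2))


def bootstrap_support(
    alignment: Alignment,
    n: int = 1000,
    seed: int = 0,
    distance_model: str = "p_distance",
) -> TreeNode:
    """NJ tree with bootstrap supports from alignment-column resampling.

    The point tree is NJ on the full alignment's distances.  For each of
    ``n`` replicates, alignment columns are resampled with replacement,
    complete deletion and NJ are re-run, and each internal edge of the
    point tree is scored by the percentage of replicate trees containing
    its bipartition.  Supports are stored on internal nodes as
    ``node.support`` and mirrored into ``node.name`` so they appear as
    internal labels in Newick output.
    """
    if n < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    tree = neighbor_joining(pairwise_distance(alignment, model=distance_model))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in _bipartitions(tree)}
    arr = alignment.to_array()
    ncols = arr.shape[1]
    rng = np.random.default_rng(seed)
    done = 0
    while done < n:
        cols = rng.integers(0, ncols, size=ncols)
        sub = Alignment(
            labels=list(alignment.labels),
            sequences=["".join(row) for row in arr[:, cols].astype("U1")],
        )
        try:
            rep = neighbor_joining(pairwise_distance(sub, model=distance_model))
        except ValueError:
            continue  # degenerate resample (e.g. all columns gapped)
        rep_bps = _bipartitions(rep)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
        done += 1
    tips = {t.name for t in tree.tips()}
    anchor = min(tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = frozenset(tips - side)
        if side in counts:
            node.support = 100.0 * counts[side] / n
            node.name = f"{node.support:g}"
    return tree


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Patristic distances: sum of branch lengths along each tip-to-tip path."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("tree has branches without lengths")
    return tree.tip_tip_distances()


def normalize_distances(dm: DistanceMatrix) -> DistanceMatrix:
    """Rescale so the maximum off-diagonal distance is exactly 1."""
    _check_square(dm)
    dmax = dm.data.max()
    if dmax <= 0:
        raise ValueError("cannot normalize an all-zero distance matrix")
    return DistanceMatrix(dm.data / dmax, ids=dm.ids)


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize a tree to Newick; write to ``path`` if given."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source) -> TreeNode:
    """Parse Newick text (or read a file path) into a tree."""
    text = str(source)
    if "(" not in text and ";" not in text:  # looks like a path
        with open(source) as fh:
            text = fh.read()
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio NewickFormatError carries position info
        raise ValueError(f"malformed Newick: {exc}") from exc
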