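"""Distance-based phylogenetics for clade-structure checks.

The survey's clade claims (truncated TPPPs embedded as a sub-clade inside
long-type TPPPs; short- and long-type unambiguously separated) are assessed
as topological properties of neighbor-joining trees built on
identity-derived distances, a deterministic desk-scale stand-in for Bayesian
MCMC tree inference. NJ is consistent on additive matrices, which the test
suite exploits as an oracle.

Containers are scikit-bio's: :class:`skbio.DistanceMatrix` and
:class:`skbio.TreeNode` (newick serialization included).
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .architecture import pairwise_align_stats
from .io import ProteinRecord


def distance_matrix(
    records: Sequence[ProteinRecord],
    aligner: Callable[[ProteinRecord, ProteinRecord], tuple[float, float]] = pairwise_align_stats,
) -> DistanceMatrix:
    """Pairwise distances d = 1 - identity/100 from global alignment."""
    if len(records) < 3:
        raise ValueError("need at least 3 records for a distance matrix")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in distance matrix input")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            identity, _ = aligner(records[i], records[j])
            d[i, j] = d[j, i] = 1.0 - identity / 100.0
    return DistanceMatrix(d, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; deterministic given the input matrix.

    Negative branch lengths (possible on non-additive input) are clamped to
    zero with a warning.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # validates symmetry / zero diagonal
    tree = nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch length(s) to 0", stacklevel=2)
    return tree


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """All leaf bipartition sides of the (unrooted) tree, singletons included."""
    tips = frozenset(t.name for t in tree.tips())
    splits = {frozenset(s) for s in tree.subsets()}
    splits |= {frozenset([t]) for t in tips}
    return splits


def is_monophyletic(tree: TreeNode, leaf_subset: set[str], outgroup: str) -> bool:
    """True iff some edge, viewed from ``outgroup``, separates exactly ``leaf_subset``."""
    tips = {t.name for t in tree.tips()}
    unknown = (set(leaf_subset) | {outgroup}) - tips
    if unknown:
        raise ValueError(f"leaves not in tree: {sorted(unknown)}")
    target = frozenset(leaf_subset)
    if target == frozenset(tips - {outgroup}):
        return True
    for side in tree_splits(tree):
        oriented = frozenset(tips) - side if outgroup in side else side
        if oriented == target:
            return True
    return False
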