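"""Distance-based clustering of gametes/hybrids: Euclidean dose distances
and a neighbor-joining tree with newick output."""

from __future__ import annotations

import math

import numpy as np
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import TreeNode, nj

from .data import DoseMatrix


class DiversityError(ValueError):
    pass


def euclidean_distances(m: DoseMatrix) -> tuple[list[str], np.ndarray]:
    """Pairwise Euclidean distance on dose vectors over co-observed markers.

    Each pair's distance is rescaled by sqrt(n_markers / n_co_observed) so
    that pairs with missing data are comparable to fully observed ones.
    """
    if m.n_samples < 2:
        raise DiversityError("need at least two samples")
    x = m.dose
    obs = ~np.isnan(x)
    n = m.n_samples
    total = m.n_markers
    d = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs
        shared = both.sum(axis=1)
        if (shared[:i] == 0).any():
            j = int(np.flatnonzero(shared[:i] == 0)[0])
            raise DiversityError(
                f"no co-observed markers for pair ({m.samples[i]}, {m.samples[j]})"
            )
        diff = np.where(both, x[i] - x, 0.0)
        ss = (diff ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d[i] = np.sqrt(ss * total / np.maximum(shared, 1))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return list(m.samples), d


def nj_tree(ids: list[str], d: np.ndarray) -> tuple[TreeNode, str]:
    """Saitou-Nei neighbor joining; returns the tree and newick text.

    Negative branch lengths are set to zero with the deficit moved to the
    adjacent branch (the scikit-bio convention). Branch lengths in the
    newick string carry 6 significant digits.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or len(ids) != d.shape[0]:
        raise DiversityError("distance matrix shape inconsistent with ids")
    if not np.allclose(d, d.T, atol=1e-9):
        raise DiversityError("distance matrix is not symmetric")
    if len(ids) < 3:
        raise DiversityError("need at least three taxa for neighbor joining")
    d = (d + d.T) / 2.0  # exact symmetry for downstream strict checks
    np.fill_diagonal(d, 0.0)
    dm = SkbioDistanceMatrix(d, ids)
    tree = nj(dm, neg_as_zero=True)
    newick = _to_newick(tree)
    return tree, newick


def _to_newick(tree: TreeNode) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            label = node.name or ""
        else:
            label = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.length is not None:
            label += f":{node.length:.6g}"
        return label

    return fmt(tree) + ";"


def tree_path_distances(tree: TreeNode, ids: list[str]) -> np.ndarray:
    """Patristic (path-length) distances between the named tips."""
    n = len(ids)
    out = np.zeros((n, n))
    tip_dm = tree.tip_tip_distances(endpoints=ids)
    for i in range(n):
        for j in range(n):
            out[i, j] = tip_dm[ids[i], ids[j]]
    return out
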