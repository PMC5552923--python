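"""Structured relatedness matrices for phylogenetic random effects.

The species random effects in the crossing model have covariance
``sigma^2 * A`` where ``A`` encodes shared evolutionary history.  Two
constructions are supported:

* from an ultrametric phylogeny: ``A_ij = depth(MRCA(i, j)) / T`` with
  ``T`` the total tree depth, so ``A`` is a correlation-scaled matrix
  with unit diagonal and off-diagonals in [0, 1];
* from a pairwise genetic-distance matrix ``D``: ``A_ij = 1 - D_ij``,
  which mirrors the relatedness convention (values near 1 = close
  relatives) but is not guaranteed positive semi-definite, hence the
  generalized-inverse fallback in :func:`stable_inverse`.

Also here: pendant-edge ultrametricization and the tree-grafting
procedure that splices a better-resolved clade from a donor phylogeny
into a backbone phylogeny, rescaling donor branch lengths so the grafted
clade keeps the backbone's clade depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "RelatednessMatrix",
    "distance_to_relatedness",
    "graft_clade",
    "leaf_depths",
    "stable_inverse",
    "tree_depth",
    "tree_to_relatedness",
    "ultrametricize",
]

# Trees are represented as dendropy objects throughout.
Phylogeny = dendropy.Tree


@dataclass
class RelatednessMatrix:
    """Square symmetric relatedness matrix with ordered taxon labels.

    Attributes
    ----------
    labels
        Taxon labels in row/column order.
    A
        The relatedness matrix; symmetric with unit diagonal.
    source
        ``"tree"`` or ``"one_minus_distance"``.
    generalized_inverse_used
        Set by :func:`stable_inverse` when the Moore-Penrose
        pseudoinverse had to be used because ``A`` is singular.
    """

    labels: list[str]
    A: np.ndarray
    source: str
    generalized_inverse_used: bool = field(default=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("relatedness matrix must be square")
        if len(self.labels) != self.A.shape[0]:
            raise ValueError("label count does not match matrix dimension")
        if not np.allclose(self.A, self.A.T, atol=1e-8):
            raise ValueError("relatedness matrix must be symmetric")
        if not np.allclose(np.diag(self.A), 1.0, atol=1e-8):
            raise ValueError("relatedness matrix must have unit diagonal")

    def submatrix(self, labels: list[str]) -> np.ndarray:
        """Extract the sub-matrix for ``labels`` in the given order."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"taxa absent from relatedness matrix: {missing}")
        idx = np.array([index[lab] for lab in labels])
        return self.A[np.ix_(idx, idx)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.labels, columns=self.labels)


def leaf_depths(tree: Phylogeny) -> dict[str, float]:
    """Root-to-tip path lengths keyed by tip label."""
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label if leaf.taxon else str(id(leaf))] = d
    return depths


def tree_depth(tree: Phylogeny) -> float:
    """Maximum root-to-tip path length."""
    depths = leaf_depths(tree)
    return max(depths.values()) if depths else 0.0


def ultrametricize(tree: Phylogeny) -> Phylogeny:
    """Extend pendant edges so all root-to-tip depths equal the maximum.

    Internal branch lengths — the shared history that the relatedness
    matrix encodes — are never touched; only terminal edges grow.
    Topology is unchanged.  A single-tip or already-ultrametric tree is
    returned as an unmodified copy.
    """
    out = tree.clone(depth=1)
    depths = leaf_depths(out)
    if not depths:
        return out
    target = max(depths.values())
    for leaf in out.leaf_node_iter():
        if leaf.parent_node is None:
            continue  # single-tip tree: the tip is the root
        label = leaf.taxon.label if leaf.taxon else str(id(leaf))
        gap = target - depths[label]
        if gap > 0:
            leaf.edge.length = (leaf.edge.length or 0.0) + gap
    return out


def _require_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> float:
    depths = leaf_depths(tree)
    T = max(depths.values())
    if T <= 0:
        raise ValueError("tree has zero depth; relatedness undefined")
    if max(depths.values()) - min(depths.values()) > rel_tol * T:
        raise ValueError(
            "tree is not ultrametric (root-to-tip depths differ); "
            "apply ultrametricize() first"
        )
    return T


def graft_clade(
    backbone: Phylogeny, donor: Phylogeny, clade_tips: set[str]
) -> Phylogeny:
    """Replace a monophyletic backbone clade with a donor phylogeny.

    Donor branch lengths are multiplied by
    ``(backbone clade depth) / (donor depth)`` so that the grafted clade
    retains the depth the clade had in the backbone; with both inputs
    ultrametric the result is ultrametric.  This is how a sparse
    backbone tree is enriched with better-resolved relationships for a
    species group available in a second tree.

    Parameters
    ----------
    backbone
        Ultrametric tree supplying the deep structure.
    donor
        Ultrametric tree whose topology replaces the clade.
    clade_tips
        Tip labels forming a monophyletic group in ``backbone``.
    """
    clade_tips = set(clade_tips)
    _require_ultrametric(backbone)
    _require_ultrametric(donor)

    out = backbone.clone(depth=1)
    out.is_rooted = True  # grafting is defined on rooted trees
    taxa = [t for t in out.taxon_namespace if t.label in clade_tips]
    if len(taxa) != len(clade_tips):
        found = {t.label for t in taxa}
        raise ValueError(f"tips absent from backbone: {sorted(clade_tips - found)}")
    mrca = out.mrca(taxa=taxa)
    spanned = {lf.taxon.label for lf in mrca.leaf_iter()}
    if spanned != clade_tips:
        raise ValueError(
            "clade tips are not monophyletic in the backbone; the spanned "
            f"clade also contains {sorted(spanned - clade_tips)}"
        )

    # depth from mrca down to its tips = total depth minus depth of mrca
    depth_of_mrca = 0.0
    node = mrca
    while node.parent_node is not None:
        depth_of_mrca += node.edge.length or 0.0
        node = node.parent_node
    clade_depth = tree_depth(out) - depth_of_mrca

    donor_depth = tree_depth(donor)
    if donor_depth <= 0:
        raise ValueError("donor tree has zero depth; cannot rescale")
    factor = clade_depth / donor_depth

    scaled = donor.clone(depth=1)
    for edge in scaled.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor

    for child in list(mrca.child_nodes()):
        mrca.remove_child(child)
    mrca.taxon = None
    for child in list(scaled.seed_node.child_nodes()):
        scaled.seed_node.remove_child(child)
        mrca.add_child(child)

    out.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return out


def tree_to_relatedness(tree: Phylogeny) -> RelatednessMatrix:
    """Relatedness from shared branch lengths of an ultrametric tree.

    For tips ``i != j``, ``A_ij = depth(MRCA(i, j)) / T`` where ``T`` is
    the total depth; the diagonal is 1.  On an ultrametric tree the MRCA
    depth equals ``T - patristic(i, j) / 2``, which is what is computed.
    The result is positive semi-definite (it is a scaled coalescent-style
    covariance).
    """
    T = _require_ultrametric(tree)
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    taxon_by_label = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    A = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxon_by_label[labels[i]], taxon_by_label[labels[j]])
            mrca_depth = T - d / 2.0
            A[i, j] = A[j, i] = max(mrca_depth, 0.0) / T
    return RelatednessMatrix(labels=labels, A=A, source="tree")


def distance_to_relatedness(
    D: pd.DataFrame, floor: bool = False
) -> RelatednessMatrix:
    """Relatedness ``A = 1 - D`` from a pairwise genetic-distance matrix.

    Distances of 0 mean identical taxa (``A = 1``); the farther apart
    two taxa, the closer ``A`` gets to 0.  Distances above 1 produce
    negative relatedness entries, which are kept with a warning unless
    ``floor=True`` clamps them to 0.  Positive semi-definiteness is not
    guaranteed and not asserted; downstream code uses a generalized
    inverse when needed.
    """
    labels = [str(lab) for lab in D.index]
    if list(D.columns.astype(str)) != labels:
        raise ValueError("distance matrix row and column labels differ")
    M = D.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(M)) > 1e-8):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(M < 0):
        raise ValueError("negative distances are not allowed")
    A = 1.0 - M
    np.fill_diagonal(A, 1.0)
    if np.any(A < 0):
        if floor:
            A = np.clip(A, 0.0, None)
            np.fill_diagonal(A, 1.0)
        else:
            warnings.warn(
                "distances exceed 1; resulting relatedness entries are "
                "negative (pass floor=True to clamp to 0)",
                stacklevel=2,
            )
    return RelatednessMatrix(labels=labels, A=A, source="one_minus_distance")


def stable_inverse(A: RelatednessMatrix | np.ndarray) -> np.ndarray:
    """Inverse of a symmetric matrix, falling back to the pseudoinverse.

    If the smallest eigenvalue exceeds the numerical rank tolerance
    (``max_dim * eps * largest singular value``), the ordinary inverse
    is returned.  Otherwise the Moore-Penrose pseudoinverse is used and,
    when the input is a :class:`RelatednessMatrix`, its
    ``generalized_inverse_used`` flag is set.  This mirrors the use of a
    generalized inverse for 1 - D relatedness matrices, which are often
    singular or indefinite.
    """
    holder = A if isinstance(A, RelatednessMatrix) else None
    M = A.A if holder is not None else np.asarray(A, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    eigvals = np.linalg.eigvalsh(M)
    tol = M.shape[0] * np.finfo(float).eps * np.max(np.abs(eigvals))
    if np.min(eigvals) > tol:
        return np.linalg.inv(M)
    inv = np.linalg.pinv(M, hermitian=True)
    if holder is not None:
        holder.generalized_inverse_used = True
    return inv
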