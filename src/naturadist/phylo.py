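"""Rooted-tree utilities: edge indexing, Faith's PD and shared-branch partitions.

Faith's phylogenetic diversity of a species set is the total branch length of
the minimal subtree connecting the set *and the root* (the root path is
included, so a single-species community has PD equal to its root-to-tip
distance). Branch-sharing between two communities partitions total length into
the part common to both root-spanning subtrees (A) and the parts exclusive to
each (B, C); those quantities drive the phylogenetic Simpson dissimilarity in
:mod:`naturadist.beta_diversity`.
"""

from __future__ import annotations

import numpy as np
import dendropy

__all__ = ["TreeIndex", "faith_pd", "shared_branch_lengths"]


class UnknownTaxonError(KeyError):
    """A queried species is not a tip of the indexed tree."""


class TreeIndex:
    """Flat edge-table view of a rooted dendropy tree.

    Precomputes, for every edge, the set of tips descending through it, so that
    PD and branch-partition queries reduce to boolean matrix operations.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree`` with branch lengths. A missing length
        (e.g. the root edge) counts as 0.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        tips = [lf for lf in tree.leaf_node_iter()]
        self.tip_labels = [lf.taxon.label for lf in tips]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("duplicate tip labels in tree")
        self.tip_pos = {lab: i for i, lab in enumerate(self.tip_labels)}
        n_tips = len(tips)

        nodes = list(tree.preorder_node_iter())
        node_pos = {id(nd): i for i, nd in enumerate(nodes)}
        n_edges = len(nodes)  # one (possibly zero-length) edge per node
        lengths = np.zeros(n_edges)
        # tip_desc[e, t] True if tip t lies below edge e
        tip_desc = np.zeros((n_edges, n_tips), dtype=bool)
        for nd in reversed(nodes):  # postorder over the preorder list
            e = node_pos[id(nd)]
            lengths[e] = nd.edge.length or 0.0
            if nd.is_leaf():
                tip_desc[e, self.tip_pos[nd.taxon.label]] = True
            else:
                for ch in nd.child_nodes():
                    tip_desc[e] |= tip_desc[node_pos[id(ch)]]
        self.edge_lengths = lengths
        self.tip_desc = tip_desc
        self.total_length = float(lengths.sum())

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_mask(self, species: "set[str] | list[str]") -> np.ndarray:
        mask = np.zeros(self.n_tips, dtype=bool)
        for sp in species:
            try:
                mask[self.tip_pos[sp]] = True
            except KeyError:
                raise UnknownTaxonError(f"species {sp!r} is not a tip of the tree") from None
        return mask

    def edge_mask(self, tip_mask: np.ndarray) -> np.ndarray:
        """Edges of the minimal root-spanning subtree of the masked tips."""
        return self.tip_desc[:, tip_mask].any(axis=1)


def faith_pd(index: TreeIndex, species) -> float:
    """Faith's PD of ``species`` (root path included)."""
    if isinstance(species, np.ndarray) and species.dtype == bool:
        mask = species
    else:
        mask = index.tip_mask(species)
    if not mask.any():
        raise ValueError("Faith's PD is undefined for an empty species set")
    return float(index.edge_lengths[index.edge_mask(mask)].sum())


def shared_branch_lengths(index: TreeIndex, set_x, set_y):
    """Partition branch length between two communities' root-spanning subtrees.

    Returns ``(A, B, C)``: length common to both subtrees, exclusive to x,
    exclusive to y. Satisfies ``A + B = PD(x)`` and ``A + C = PD(y)``.
    """
    mx = set_x if (isinstance(set_x, np.ndarray) and set_x.dtype == bool) else index.tip_mask(set_x)
    my = set_y if (isinstance(set_y, np.ndarray) and set_y.dtype == bool) else index.tip_mask(set_y)
    if not mx.any() or not my.any():
        raise ValueError("communities must be non-empty")
    ex = index.edge_mask(mx)
    ey = index.edge_mask(my)
    lengths = index.edge_lengths
    a = float(lengths[ex & ey].sum())
    b = float(lengths[ex & ~ey].sum())
    c = float(lengths[ey & ~ex].sum())
    return a, b, c


def node_depth(node) -> float:
    """Distance from ``node`` to its (deepest) descendant tip."""
    best = 0.0
    for lf in node.leaf_iter():
        d = 0.0
        nd = lf
        while nd is not node:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        best = max(best, d)
    return best
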