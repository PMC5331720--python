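"""Rooted-tree containers and Newick I/O.

Trees cross the public interface as :class:`dendropy.Tree` objects; the
numerical code (pruning likelihoods, trait simulation, the D statistic)
runs on :class:`TreeArrays`, a flat index-based view in which tips carry
ids ``0 .. n_tips-1`` and internal nodes are numbered in postorder, so the
root always has the highest id and ``range(n_tips, n_nodes)`` is a valid
bottom-up sweep while ``reversed(range(n_nodes))`` is top-down.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

#: Branch lengths of exactly zero are perturbed to this value (My) so that
#: transition matrices stay non-degenerate.
MIN_BRANCH = 1e-8


class TreeArrays:
    """Flat array view of a rooted tree with branch lengths in My."""

    def __init__(
        self,
        parent: np.ndarray,
        edge_length: np.ndarray,
        tip_labels: list[str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        if np.any(self.edge_length[: self.n_nodes - 1] < 0):
            raise ValueError("negative branch length")
        if len(set(self.tip_labels)) != self.n_tips:
            raise ValueError("tip labels are not unique")
        self.tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            self.children[self.parent[v]].append(v)
        self.root = self.n_nodes - 1

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeArrays":
        nodes = list(tree.postorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        ids: dict[int, int] = {}
        for i, nd in enumerate(tips):
            ids[id(nd)] = i
        for j, nd in enumerate(internals):
            ids[id(nd)] = len(tips) + j
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n)
        n_zero = 0
        for nd in nodes:
            u = ids[id(nd)]
            if nd.parent_node is not None:
                parent[u] = ids[id(nd.parent_node)]
                el = nd.edge.length
                if el is None:
                    el = 0.0
                if el < 0:
                    raise ValueError("negative branch length in tree")
                if el == 0.0:
                    el = MIN_BRANCH
                    n_zero += 1
                blen[u] = el
        if n_zero:
            warnings.warn(
                f"{n_zero} zero-length branches perturbed to {MIN_BRANCH} My",
                stacklevel=2,
            )
        labels = [
            (nd.taxon.label if nd.taxon is not None else f"tip{i}")
            for i, nd in enumerate(tips)
        ]
        return cls(parent, blen, labels)

    # -- geometry ------------------------------------------------------

    def depths(self) -> np.ndarray:
        """Root-to-node distances, indexed by node id."""
        d = np.zeros(self.n_nodes)
        for u in reversed(range(self.n_nodes - 1)):
            d[u] = d[self.parent[u]] + self.edge_length[u]
        return d

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        td = self.depths()[: self.n_tips]
        return bool(td.max() - td.min() <= tol * max(1.0, td.max()))

    def vcv(self) -> np.ndarray:
        """Shared-branch-length (phylogenetic covariance) matrix over tips."""
        depth = self.depths()
        C = np.zeros((self.n_tips, self.n_tips))
        tipsets: list[np.ndarray | None] = [None] * self.n_nodes
        for u in range(self.n_nodes):
            if u < self.n_tips:
                tipsets[u] = np.array([u])
            else:
                kids = [tipsets[v] for v in self.children[u]]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        C[np.ix_(kids[a], kids[b])] = depth[u]
                        C[np.ix_(kids[b], kids[a])] = depth[u]
                tipsets[u] = np.concatenate(kids)
        np.fill_diagonal(C, depth[: self.n_tips])
        return C


def as_arrays(tree) -> TreeArrays:
    """Coerce a dendropy tree (or pass through a TreeArrays) to arrays."""
    if isinstance(tree, TreeArrays):
        return tree
    return TreeArrays.from_dendropy(tree)


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
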