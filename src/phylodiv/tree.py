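"""Rooted phylogenetic tree container used by the diversity computations.

The tree is stored as flat arrays in preorder (root first, every parent
before its children), which makes the branch-level bookkeeping of the
entropy decomposition a handful of vectorized operations:

* frequencies are accumulated leaf-to-root through a sparse
  leaf-membership matrix (``leaf_matrix``),
* a lineage (an internal node plus all its descendants) is a contiguous
  preorder slice (``subtree_slice``).

Every node is addressable by a deterministic name: its own label when the
newick carries one, and ``L<preorder index>`` always.  Internal-node
labels are preserved on round-trip so that lineage names in reports match
the exported tree.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterator, Sequence

import dendropy
import numpy as np
from scipy import sparse

from .errors import ValidationError

__all__ = ["PhyloTree"]


class PhyloTree:
    """Rooted tree with branch lengths; leaves labelled by OTU ids.

    Parameters are flat preorder arrays; use :meth:`from_newick` rather
    than constructing directly.
    """

    def __init__(
        self,
        parent: np.ndarray,
        lengths: np.ndarray,
        labels: Sequence[str | None],
    ):
        self.parent = np.asarray(parent, dtype=np.intp)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if n == 0 or self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise ValidationError("nodes must be in preorder with a single root")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValidationError("parent indices must precede children (preorder)")
        if np.any(self.lengths < 0):
            raise ValidationError("branch lengths must be nonnegative")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.is_leaf = np.fromiter(
            (len(c) == 0 for c in self.children), dtype=bool, count=n
        )
        leaf_idx = np.flatnonzero(self.is_leaf)
        self.leaf_nodes = leaf_idx
        self.leaf_ids = [self.labels[i] for i in leaf_idx]
        if any(not lab for lab in self.leaf_ids):
            raise ValidationError("every leaf must carry a non-empty label")
        if len(set(self.leaf_ids)) != len(self.leaf_ids):
            raise ValidationError("duplicate leaf labels")
        # subtree size -> contiguous preorder slice per lineage
        size = np.ones(n, dtype=np.intp)
        for i in range(n - 1, 0, -1):
            size[self.parent[i]] += size[i]
        self._subtree_size = size
        self._leaf_matrix: sparse.csr_matrix | None = None
        self._name_index: dict[str, int] | None = None

    # ------------------------------------------------------------------
    # construction / serialization
    # ------------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick_text: str) -> "PhyloTree":
        """Parse a rooted newick string.

        Missing branch lengths default to 0 with a warning; duplicate
        leaf labels or malformed newick raise :class:`ValidationError`.
        """
        try:
            dtree = dendropy.Tree.get(
                data=newick_text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            if "Duplicate taxon labels" in str(exc):
                raise ValidationError(f"duplicate leaf labels: {exc}") from exc
            raise ValidationError(f"malformed newick: {exc}") from exc
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.empty(len(nodes), dtype=np.intp)
        lengths = np.zeros(len(nodes))
        labels: list[str | None] = []
        missing = 0
        for i, nd in enumerate(nodes):
            parent[i] = -1 if nd.parent_node is None else index[id(nd.parent_node)]
            if i > 0:
                if nd.edge.length is None:
                    missing += 1
                else:
                    lengths[i] = nd.edge.length
            if nd.taxon is not None:
                labels.append(nd.taxon.label)
            else:
                labels.append(nd.label or None)
        if missing:
            warnings.warn(
                f"{missing} branch length(s) missing in newick; set to 0",
                stacklevel=2,
            )
        return cls(parent, lengths, labels)

    def to_newick(self, name_internal: bool = False) -> str:
        """Serialize to newick. With ``name_internal`` every unlabelled
        internal node is written with its deterministic ``L<i>`` name, so
        exported annotations resolve against the exported tree."""
        buf = io.StringIO()

        def write(i: int) -> None:
            if self.children[i]:
                buf.write("(")
                for k, c in enumerate(self.children[i]):
                    if k:
                        buf.write(",")
                    write(c)
                buf.write(")")
                lab = self.labels[i]
                if lab is None and name_internal:
                    lab = self.node_name(i)
                if lab:
                    buf.write(_quote(lab))
            else:
                buf.write(_quote(self.labels[i]))
            if i != 0:
                buf.write(f":{self.lengths[i]:.10g}")

        write(0)
        buf.write(";")
        return buf.getvalue()

    # ------------------------------------------------------------------
    # topology helpers
    # ------------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_leaves(self) -> int:
        return self.leaf_nodes.size

    def node_name(self, i: int) -> str:
        return self.labels[i] if self.labels[i] else f"L{i}"

    def find_node(self, name: str) -> int:
        """Resolve a node by label or by deterministic ``L<i>`` name."""
        if self._name_index is None:
            idx: dict[str, int] = {f"L{i}": i for i in range(self.n_nodes)}
            for i, lab in enumerate(self.labels):
                if lab:
                    idx.setdefault(lab, i)
            self._name_index = idx
        try:
            return self._name_index[name]
        except KeyError:
            raise KeyError(f"no node named {name!r} in tree") from None

    def subtree_slice(self, i: int) -> slice:
        """Preorder slice covering node ``i`` and all its descendants."""
        return slice(i, i + int(self._subtree_size[i]))

    def leaf_matrix(self) -> sparse.csr_matrix:
        """Sparse (n_nodes x n_leaves) indicator: node i ancestor-or-self
        of leaf j. Multiplying a per-leaf vector by it accumulates
        descendant abundance onto every branch."""
        if self._leaf_matrix is None:
            rows, cols = [], []
            for j, leaf in enumerate(self.leaf_nodes):
                i = int(leaf)
                while i != -1:
                    rows.append(i)
                    cols.append(j)
                    i = int(self.parent[i])
            data = np.ones(len(rows))
            self._leaf_matrix = sparse.csr_matrix(
                (data, (rows, cols)), shape=(self.n_nodes, self.n_leaves)
            )
        return self._leaf_matrix

    def preorder(self) -> Iterator[int]:
        return iter(range(self.n_nodes))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_leaves={self.n_leaves}, n_nodes={self.n_nodes})"


def _quote(label: str | None) -> str:
    if label is None:
        return ""
    if any(c in label for c in "():;, '\t\n[]"):
        return "'" + label.replace("'", "''") + "'"
    return label
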