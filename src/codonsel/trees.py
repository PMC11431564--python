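"""Phylogenetic tree container used by the likelihood engine.

Trees are parsed and serialized with dendropy but held internally as flat
parent/child index arrays, which is what the pruning recursion, branch-length
optimization, and the simulator actually consume.  Branch lengths are in
expected substitutions per codon.  For likelihood purposes the canonical form
is unrooted: a basal bifurcation is collapsed on input, so a tree over n >= 3
taxa has 2n-3 branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import ReconciliationError, ValidationFailure


@dataclass
class PhyloTree:
    """Tree over ``taxa`` stored as index arrays.

    Nodes 0..n_leaves-1 are the leaves (aligned with ``taxa``); internal nodes
    follow; the root is the last node in ``postorder``.  ``lengths[v]`` is the
    length of the branch above node v (0.0 for the root).
    """

    taxa: list[str]
    parent: np.ndarray
    lengths: np.ndarray
    children: list[list[int]]
    postorder: list[int]
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.lengths < 0):
            raise ValidationFailure("negative branch length")
        if not self.node_labels:
            self.node_labels = [
                self.taxa[v] if v < self.n_leaves else f"node{v}"
                for v in range(self.n_nodes)
            ]

    # ------------------------------------------------------------------ basics
    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    @property
    def branch_nodes(self) -> list[int]:
        """Nodes that subtend a branch (everything except the root)."""
        return [v for v in self.postorder if v != self.root]

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def total_length(self) -> float:
        return float(sum(self.lengths[v] for v in self.branch_nodes))

    def is_leaf(self, v: int) -> bool:
        return v < self.n_leaves

    def leaf_set(self, v: int) -> frozenset[str]:
        """Taxon labels below node v (v included if a leaf)."""
        if self.is_leaf(v):
            return frozenset([self.taxa[v]])
        out: set[str] = set()
        stack = [v]
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.add(self.taxa[u])
            else:
                stack.extend(self.children[u])
        return frozenset(out)

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        return PhyloTree(
            taxa=list(self.taxa),
            parent=self.parent.copy(),
            lengths=np.asarray(lengths, dtype=float).copy(),
            children=[list(c) for c in self.children],
            postorder=list(self.postorder),
            node_labels=list(self.node_labels),
        )

    def validate_against(self, taxa) -> None:
        """Check leaf labels equal the alignment's taxon set."""
        mine, theirs = set(self.taxa), set(taxa)
        if mine != theirs:
            diff = sorted(mine ^ theirs)
            raise ReconciliationError(
                f"tree and alignment taxa differ; symmetric difference: {diff}"
            )

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        root = tree.seed_node
        kids = root.child_nodes()
        if len(kids) == 2 and len(tree.leaf_nodes()) >= 3:
            # collapse the basal bifurcation -> canonical unrooted form
            internal = next((c for c in kids if not c.is_leaf()), kids[0])
            other = kids[1] if internal is kids[0] else kids[0]
            merged = (other.edge.length or 0.0) + (internal.edge.length or 0.0)
            root.remove_child(internal)
            for gc in list(internal.child_nodes()):
                internal.remove_child(gc)
                root.add_child(gc)
            other.edge.length = merged
        leaves = [lf for lf in tree.leaf_node_iter()]
        taxa = [lf.taxon.label for lf in leaves]
        if len(set(taxa)) != len(taxa):
            raise ValidationFailure("duplicate leaf labels in tree")
        index: dict[int, int] = {id(lf): i for i, lf in enumerate(leaves)}
        internal_nodes = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        for k, nd in enumerate(internal_nodes):
            index[id(nd)] = len(taxa) + k
        n = len(taxa) + len(internal_nodes)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n, dtype=float)
        children: list[list[int]] = [[] for _ in range(n)]
        labels = [""] * n
        for nd in tree.postorder_node_iter():
            v = index[id(nd)]
            labels[v] = (
                nd.taxon.label
                if nd.taxon is not None
                else (nd.label or f"node{v}")
            )
            if nd.parent_node is not None:
                parent[v] = index[id(nd.parent_node)]
                children[parent[v]].append(v)
                lengths[v] = nd.edge.length if nd.edge.length is not None else 0.0
        post = [index[id(nd)] for nd in tree.postorder_node_iter()]
        return cls(
            taxa=taxa,
            parent=parent,
            lengths=lengths,
            children=children,
            postorder=post,
            node_labels=labels,
        )

    @classmethod
    def from_newick_string(cls, s: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=s, schema="newick")
        return cls.from_dendropy(tree)

    @classmethod
    def from_newick_file(cls, path) -> "PhyloTree":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls.from_dendropy(tree)

    def to_newick(self, annotations: dict[int, str] | None = None) -> str:
        """Serialize with branch lengths; optional per-branch comment strings
        (e.g. omega estimates) are emitted as ``[&...]`` after the length."""

        def emit(v: int) -> str:
            if self.is_leaf(v):
                body = self.taxa[v]
            else:
                body = "(" + ",".join(emit(c) for c in self.children[v]) + ")"
            if v == self.root:
                return body
            s = f"{body}:{self.lengths[v]:.10g}"
            if annotations and v in annotations:
                s += f"[&{annotations[v]}]"
            return s

        return emit(self.root) + ";"


def read_newick(path) -> PhyloTree:
    """Read a newick tree file (module-level convenience wrapper)."""
    return PhyloTree.from_newick_file(path)
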