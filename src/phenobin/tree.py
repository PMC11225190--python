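"""Reference trees with a stable edge registry.

Trees are stored rooted for bookkeeping (a degree-2 root subdividing one
unrooted edge); every analysis quantity is invariant to the root position.
Each non-root node owns the edge to its parent; edge ids are assigned by
post-order traversal and are therefore stable across re-reads of the same
newick string. On a binary tree with n terminals there are 2n - 2 edges;
the two root-adjacent edges represent the same unrooted edge and always
carry equal placement scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .errors import (
    DuplicateLabelError,
    OverlappingCladesError,
    PolytomyError,
    TreeFormatError,
)


@dataclass
class ReferenceTree:
    """Array-backed rooted binary tree over terminal labels.

    Attributes
    ----------
    parent:
        Parent node id per node (-1 for the root).
    children:
        Child id lists per node (empty for terminals).
    blen:
        Length of the edge above each node (0.0 for the root).
    leaf_label:
        node id -> terminal label for terminals.
    edge_of_node / node_of_edge:
        The stable post-order edge registry: every non-root node owns one
        edge id in [0, n_edges).
    clade_map:
        Named clades as sets of terminal labels.
    """

    parent: np.ndarray
    children: list[list[int]]
    blen: np.ndarray
    leaf_label: dict[int, str]
    clade_map: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        if np.any(self.blen < 0):
            raise TreeFormatError("negative branch length")
        labels = list(self.leaf_label.values())
        if len(set(labels)) != len(labels):
            raise DuplicateLabelError("duplicate terminal labels")
        self.root = int(np.where(self.parent < 0)[0][0])
        self.label_to_node = {lab: n for n, lab in self.leaf_label.items()}
        # post-order node sequence (root last) and the edge registry
        self.postorder: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                self.postorder.append(node)
            else:
                stack.append((node, True))
                for c in reversed(self.children[node]):
                    stack.append((c, False))
        nonroot = [n for n in self.postorder if n != self.root]
        self.edge_of_node = {n: i for i, n in enumerate(nonroot)}
        self.node_of_edge = {i: n for n, i in self.edge_of_node.items()}
        for name, members in self.clade_map.items():
            self.clade_map[name] = frozenset(members)
            unknown = self.clade_map[name] - set(self.label_to_node)
            if unknown:
                raise TreeFormatError(
                    f"clade {name!r} names unknown terminals {sorted(unknown)}"
                )

    # -- geometry -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def terminal_labels(self) -> list[str]:
        return [self.leaf_label[n] for n in self.postorder if n in self.leaf_label]

    @property
    def n_terminals(self) -> int:
        return len(self.leaf_label)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def pendant_edge(self, label: str) -> int:
        return self.edge_of_node[self.label_to_node[label]]

    def mean_pendant_length(self) -> float:
        leaves = list(self.leaf_label)
        return float(np.mean([self.blen[n] for n in leaves]))

    def edge_lengths(self) -> np.ndarray:
        """Branch length per edge id."""
        out = np.empty(self.n_edges)
        for e, n in self.node_of_edge.items():
            out[e] = self.blen[n]
        return out

    def edge_subtree_labels(self, edge_id: int) -> frozenset[str]:
        """Terminal labels on the distal (child) side of an edge."""
        top = self.node_of_edge[edge_id]
        labels = []
        stack = [top]
        while stack:
            n = stack.pop()
            if self.is_leaf(n):
                labels.append(self.leaf_label[n])
            stack.extend(self.children[n])
        return frozenset(labels)

    def validate_clade_map(self) -> None:
        names = list(self.clade_map)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if self.clade_map[a] & self.clade_map[b]:
                    raise OverlappingCladesError(f"clades {a!r} and {b!r} overlap")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_dendropy(
        cls, dtree: dendropy.Tree, polytomy_policy: str = "reject",
        clade_map: dict[str, frozenset[str]] | None = None,
    ) -> "ReferenceTree":
        dtree = dtree.clone(depth=1)
        seed = dtree.seed_node
        # collapse a unifurcating root chain, then binarize or reject
        while len(seed.child_nodes()) == 1:
            seed = seed.child_nodes()[0]
            dtree.seed_node = seed
        for nd in dtree.preorder_node_iter():
            kids = nd.child_nodes()
            if len(kids) > 2:
                if polytomy_policy == "reject":
                    raise PolytomyError(
                        f"polytomy with {len(kids)} children (policy 'reject')"
                    )
                elif polytomy_policy == "resolve_zero_length":
                    # deterministic left-comb resolution with zero-length edges
                    while len(nd.child_nodes()) > 2:
                        kids = nd.child_nodes()
                        a, b = kids[0], kids[1]
                        new = dendropy.Node()
                        new.edge.length = 0.0
                        nd.remove_child(a)
                        nd.remove_child(b)
                        new.add_child(a)
                        new.add_child(b)
                        nd.insert_child(0, new)
                else:
                    raise ValueError(f"unknown polytomy policy {polytomy_policy!r}")
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        blen = np.zeros(len(nodes))
        children: list[list[int]] = [[] for _ in nodes]
        leaf_label: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeFormatError("unlabeled terminal")
                leaf_label[i] = nd.taxon.label
        if len(leaf_label) < 3:
            raise TreeFormatError("tree must have at least 3 terminals")
        return cls(parent, children, blen, leaf_label, clade_map=dict(clade_map or {}))

    @classmethod
    def from_newick(
        cls, newick: str, polytomy_policy: str = "reject",
        clade_map: dict[str, frozenset[str]] | None = None,
    ) -> "ReferenceTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises a zoo of parse errors
            if "duplicate" in str(exc).lower() or "multiple occurrences" in str(exc).lower():
                raise DuplicateLabelError(str(exc)) from exc
            raise TreeFormatError(f"unreadable newick: {exc}") from exc
        return cls.from_dendropy(dtree, polytomy_policy, clade_map)

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if self.is_leaf(node):
                body = self.leaf_label[node]
            else:
                body = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if node == self.root:
                return body
            return f"{body}:{self.blen[node]:.12g}"

        return render(self.root) + ";"

    # -- surgery ---------------------------------------------------------
    def prune_terminal(self, label: str) -> tuple["ReferenceTree", list[int]]:
        """Remove one terminal; return the pruned tree and its true edges.

        The true edges are the edge ids, *in the pruned tree*, onto which
        re-inserting the terminal would restore the original unrooted
        topology. This is one edge in general; when the pruned leaf was a
        child of the bookkeeping root, the merged attachment edge is split
        by the new root and both root-adjacent edges are returned.
        """
        if self.n_terminals <= 3:
            raise TreeFormatError("cannot prune below 3 terminals")
        v = self.label_to_node[label]
        p = int(self.parent[v])
        sib = [c for c in self.children[p] if c != v][0]
        keep = sorted(set(range(self.n_nodes)) - {v, p})
        remap = {old: new for new, old in enumerate(keep)}
        parent = np.full(len(keep), -1, dtype=int)
        blen = np.zeros(len(keep))
        children: list[list[int]] = [[] for _ in keep]
        leaf_label: dict[int, str] = {}
        pp = int(self.parent[p])
        for old in keep:
            new = remap[old]
            if old in self.leaf_label:
                leaf_label[new] = self.leaf_label[old]
            if old == sib:
                if pp >= 0:
                    parent[new] = remap[pp]
                    children[remap[pp]].append(new)
                    blen[new] = self.blen[sib] + self.blen[p]
                # else: sib becomes the new root (parent stays -1, blen 0)
            else:
                po = int(self.parent[old])
                if po >= 0:
                    parent[new] = remap[po]
                    blen[new] = self.blen[old]
        # rebuild child lists in original order for determinism
        children = [[] for _ in keep]
        for new, par in enumerate(parent):
            if par >= 0:
                children[par].append(new)
        for i in range(len(children)):
            children[i].sort()
        clade_map = {
            name: frozenset(m - {label})
            for name, m in self.clade_map.items()
            if len(m - {label}) > 0
        }
        pruned = ReferenceTree(parent, children, blen, leaf_label, clade_map)
        if pp >= 0:
            true_edges = [pruned.edge_of_node[remap[sib]]]
        else:
            # leaf was a root child: the attachment edge is now split by the
            # new root across its two children
            true_edges = [
                pruned.edge_of_node[c] for c in pruned.children[pruned.root]
            ]
        return pruned, true_edges


def read_tree(
    path: str | Path, polytomy_policy: str = "reject",
    clade_map: dict[str, frozenset[str]] | None = None,
) -> ReferenceTree:
    """Read a newick tree file into a :class:`ReferenceTree`."""
    return ReferenceTree.from_newick(
        Path(path).read_text(), polytomy_policy, clade_map
    )


def write_tree(tree: ReferenceTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
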