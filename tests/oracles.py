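"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming machinery:
parsimony scores come from exhaustive enumeration of ancestral states,
likelihoods from explicit summation over internal-node assignments, and
edge-insertion scores from rebuilding the extended tree as a fresh newick
string and rescoring it from scratch.
"""

import itertools

import numpy as np

from phenobin.likelihood import MkModel, mk_loglik
from phenobin.parsimony import sankoff_score
from phenobin.tree import ReferenceTree


def brute_parsimony(tree: ReferenceTree, states: dict, S: np.ndarray) -> float:
    """Minimum over all ancestral-state assignments, by enumeration."""
    k = S.shape[0]
    internals = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    best = np.inf
    for combo in itertools.product(range(k), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        total = 0.0
        feasible = True
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            p = int(tree.parent[v])
            if tree.is_leaf(v):
                s = states.get(tree.leaf_label[v])
                if s is None:
                    continue
            else:
                s = assign[v]
            total += S[assign[p], s]
        if feasible:
            best = min(best, total)
    return float(best)


def brute_loglik(tree: ReferenceTree, states: dict, model: MkModel) -> float:
    """Explicit sum over all internal-node state combinations."""
    k = model.k
    internals = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        lik = 1.0 / k  # uniform root prior
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            p = int(tree.parent[v])
            P = model.transition(float(tree.blen[v]))
            if tree.is_leaf(v):
                s = states.get(tree.leaf_label[v])
                lik *= 1.0 if s is None else P[assign[p], s]
            else:
                lik *= P[assign[p], assign[v]]
        total += lik
    return float(np.log(total))


def rebuild_newick_with_query(
    tree: ReferenceTree, edge_id: int, pendant_length: float, query_label: str = "QQ"
) -> str:
    """Newick of the tree with a query leaf attached at the edge midpoint."""
    target = tree.node_of_edge[edge_id]

    def render(node: int) -> str:
        if tree.is_leaf(node):
            body = tree.leaf_label[node]
        else:
            body = "(" + ",".join(render(c) for c in tree.children[node]) + ")"
        if node == tree.root:
            return body
        t = float(tree.blen[node])
        if node == target:
            return f"({body}:{t / 2},{query_label}:{pendant_length}):{t / 2}"
        return f"{body}:{t}"

    return render(tree.root) + ";"


def rebuild_mp_scores(tree, states, ordered, k, query_state):
    """Per-edge total steps by rebuilding and rescoring every extended tree."""
    out = []
    for e in range(tree.n_edges):
        ext = ReferenceTree.from_newick(rebuild_newick_with_query(tree, e, 0.1))
        st = dict(states)
        st["QQ"] = query_state
        out.append(sankoff_score(ext, st, ordered=ordered, n_states=k))
    return np.array(out)


def rebuild_ml_logliks(tree, states, model, query_state):
    """Per-edge attachment log-likelihood by full rebuild and pruning."""
    out = []
    for e in range(tree.n_edges):
        ext = ReferenceTree.from_newick(
            rebuild_newick_with_query(tree, e, model.pendant_length)
        )
        st = dict(states)
        st["QQ"] = query_state
        out.append(mk_loglik(ext, st, model))
    return np.array(out)
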