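"""Sankoff parsimony on discrete characters.

Characters are unordered (any change costs 1) or ordered (a change from
state i to j costs |i - j|). Besides the plain tree score, the module
computes per-edge conditional cost tables: for every edge, the minimal cost
of each side of the tree conditional on the state of a node inserted on
that edge. These tables make query insertion on every edge a single
vectorized pass, and both step matrices are metrics, so subdividing an edge
never changes the base score.
"""

from __future__ import annotations

import numpy as np

from .errors import MissingDataError, StateOutOfRangeError
from .tree import ReferenceTree


def step_matrix(k: int, ordered: bool) -> np.ndarray:
    """Unordered (Fitch-like 0/1) or ordered (|i-j|) step matrix."""
    idx = np.arange(k)
    if ordered:
        return np.abs(idx[:, None] - idx[None, :]).astype(float)
    return (idx[:, None] != idx[None, :]).astype(float)


def _leaf_costs(tree: ReferenceTree, states: dict[str, int | None], k: int) -> np.ndarray:
    """Initial cost vectors: observed leaves one-state, missing all-zero."""
    D = np.zeros((tree.n_nodes, k))
    n_obs = 0
    for node, label in tree.leaf_label.items():
        s = states.get(label)
        if s is None:
            continue
        if not (0 <= s < k):
            raise StateOutOfRangeError(f"state {s} for terminal {label!r} >= k={k}")
        D[node] = np.inf
        D[node, s] = 0.0
        n_obs += 1
    if n_obs == 0:
        raise MissingDataError("all terminals missing for this character")
    return D


def sankoff_down(
    tree: ReferenceTree, states: dict[str, int | None], S: np.ndarray
) -> np.ndarray:
    """Post-order pass: D[v, s] = min cost of the subtree at v given state s."""
    k = S.shape[0]
    D = _leaf_costs(tree, states, k)
    for v in tree.postorder:
        for c in tree.children[v]:
            D[v] += (S + D[c][None, :]).min(axis=1)
    return D


def sankoff_score(
    tree: ReferenceTree,
    states: dict[str, int | None],
    ordered: bool = False,
    n_states: int | None = None,
) -> float:
    """Minimal total steps over all ancestral-state assignments."""
    observed = [s for s in states.values() if s is not None]
    if not observed:
        raise MissingDataError("all terminals missing for this character")
    k = max(n_states or (max(observed) + 1), 2)
    D = sankoff_down(tree, states, step_matrix(k, ordered))
    return float(D[tree.root].min())


def sankoff_edge_tables(
    tree: ReferenceTree, states: dict[str, int | None], S: np.ndarray
) -> np.ndarray:
    """Per-edge conditional totals M[e, a].

    M[e, a] is the minimal number of steps of the whole tree when a new
    attachment node with state ``a`` subdivides edge ``e`` (both half-edges
    keep their step costs). Inserting a query with state q on edge e then
    costs ``min_a M[e, a] + S[a, q]``; min_a M[e, a] equals the base score
    on every edge.
    """
    k = S.shape[0]
    D = sankoff_down(tree, states, S)
    EB = np.zeros((tree.n_nodes, k))  # cost below v incl. v's edge, per top state
    for v in range(tree.n_nodes):
        EB[v] = (S + D[v][None, :]).min(axis=1)
    M = np.zeros((tree.n_edges, k))
    Uex = np.zeros((tree.n_nodes, k))
    for v in reversed(tree.postorder):  # pre-order
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        R = np.zeros(k) if p == tree.root else Uex[p].copy()
        for u in tree.children[p]:
            if u != v:
                R += EB[u]
        Uex[v] = (S + R[:, None]).min(axis=0)
        M[tree.edge_of_node[v]] = Uex[v] + EB[v]
    return M


def mp_insertion_scores(
    M: np.ndarray, S: np.ndarray, query_state: int | None
) -> np.ndarray:
    """Total tree steps per edge after inserting a query with this state."""
    if query_state is None:
        return M.min(axis=1)
    if not (0 <= query_state < S.shape[0]):
        raise StateOutOfRangeError(f"query state {query_state} out of range")
    return (M + S[:, query_state][None, :]).min(axis=1)
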