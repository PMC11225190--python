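"""Mk-model likelihood on discrete characters.

The Mk model is a k-state continuous-time Markov chain with equal exchange
rates (off-diagonal generator entries all beta) and a uniform stationary
distribution. Transition probabilities have the closed form

    P_same(t) = 1/k + (k-1)/k * exp(-k * beta * t)
    P_diff(t) = 1/k -   1/k * exp(-k * beta * t)

Log-likelihoods are computed by Felsenstein's pruning algorithm with a
uniform 1/k root prior; missing terminals carry all-ones partial vectors.
Per-edge outside/inside partials allow scoring the insertion of a query
leaf (pendant branch at the edge midpoint) on every edge in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import MissingDataError, StateOutOfRangeError
from .tree import ReferenceTree


@dataclass
class MkModel:
    """Equal-rates k-state Markov model.

    Parameters
    ----------
    k:
        Number of states (>= 2).
    beta:
        Off-diagonal substitution rate (> 0).
    pendant_length:
        Branch length used when attaching an inserted query leaf.
    """

    k: int
    beta: float
    pendant_length: float = 0.1

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    def transition(self, t: float) -> np.ndarray:
        """P(t); rows sum to 1 and P(0) is the identity."""
        k = self.k
        decay = np.exp(-k * self.beta * t)
        P = np.full((k, k), (1.0 - decay) / k)
        np.fill_diagonal(P, 1.0 / k + (k - 1) / k * decay)
        return P


def _leaf_partials(
    tree: ReferenceTree, states: dict[str, int | None], k: int
) -> np.ndarray:
    L = np.ones((tree.n_nodes, k))
    n_obs = 0
    for node, label in tree.leaf_label.items():
        s = states.get(label)
        if s is None:
            continue
        if not (0 <= s < k):
            raise StateOutOfRangeError(f"state {s} for terminal {label!r} >= k={k}")
        L[node] = 0.0
        L[node, s] = 1.0
        n_obs += 1
    if n_obs == 0:
        raise MissingDataError("all terminals missing for this character")
    return L


def _down_partials(
    tree: ReferenceTree, states: dict[str, int | None], model: MkModel
) -> np.ndarray:
    L = _leaf_partials(tree, states, model.k)
    for v in tree.postorder:
        for c in tree.children[v]:
            L[v] *= model.transition(tree.blen[c]) @ L[c]
    return L


def mk_loglik(
    tree: ReferenceTree, states: dict[str, int | None], model: MkModel
) -> float:
    """Pruning-algorithm log-likelihood with uniform root prior."""
    L = _down_partials(tree, states, model)
    return float(np.log(L[tree.root].mean()))


PROFILE_TOL = 1e-2


def fit_beta(
    tree: ReferenceTree,
    states: dict[str, int | None],
    k: int,
    pendant_length: float = 0.1,
    bounds: tuple[float, float] = (1e-4, 100.0),
    xatol: float = 1e-6,
) -> MkModel:
    """Fit the per-character rate by bounded 1-D likelihood maximization.

    A single discrete character often has a ridge-shaped likelihood in the
    rate: beyond some point, larger beta changes the log-likelihood by
    practically nothing (saturation), and the raw maximizer is an arbitrary
    point on the plateau. To keep the rate identifiable, the fit returns
    the smallest rate whose log-likelihood is within ``PROFILE_TOL`` of the
    optimum (the lower edge of the profile-likelihood plateau), found by
    bisection on the rising flank.
    """

    def lnl(beta: float) -> float:
        return mk_loglik(tree, states, MkModel(k, beta, pendant_length))

    res = minimize_scalar(
        lambda b: -lnl(b), bounds=bounds, method="bounded",
        options={"xatol": xatol},
    )
    beta_hat = float(res.x)
    target = -float(res.fun) - PROFILE_TOL
    lo, hi = bounds[0], beta_hat
    if lnl(lo) >= target:
        return MkModel(k, lo, pendant_length)
    while hi - lo > max(xatol, 1e-3 * hi):
        mid = np.sqrt(lo * hi)  # bisect on the log scale
        if lnl(mid) >= target:
            hi = mid
        else:
            lo = mid
    return MkModel(k, float(hi), pendant_length)


def ml_edge_tables(
    tree: ReferenceTree, states: dict[str, int | None], model: MkModel
) -> np.ndarray:
    """Per-edge attachment partials Med[e, a].

    Med[e, a] = P(all data | attachment node on edge e has state a), with
    the edge split into two halves of length t_e/2. Inserting a query with
    state q on a pendant branch of length tp gives likelihood
    ``Med[e] @ P(tp)[:, q]``; ``Med[e].sum()`` is the base likelihood on
    every edge.
    """
    k = model.k
    L = _down_partials(tree, states, model)
    # EB[v, s_parent] = P(data below v | parent state), across v's full edge
    EB = np.ones((tree.n_nodes, k))
    for v in range(tree.n_nodes):
        if v != tree.root:
            EB[v] = model.transition(tree.blen[v]) @ L[v]
    prior = np.full(k, 1.0 / k)
    # G[v, sp] = P(data outside subtree(v) | state at parent of v = sp),
    # excluding v's own edge, including the root prior
    G = np.zeros((tree.n_nodes, k))
    Med = np.zeros((tree.n_edges, k))
    for v in reversed(tree.postorder):  # pre-order
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        if p == tree.root:
            out = prior.copy()
        else:
            out = G[p] @ model.transition(tree.blen[p])  # transport across p's edge
        for u in tree.children[p]:
            if u != v:
                out = out * EB[u]
        G[v] = out
        Phalf = model.transition(tree.blen[v] / 2.0)
        above = G[v] @ Phalf  # outside data down to the midpoint
        below = Phalf @ L[v]  # subtree data up to the midpoint
        Med[tree.edge_of_node[v]] = above * below
    return Med


def ml_insertion_logliks(
    Med: np.ndarray, model: MkModel, query_state: int | None,
    pendant_length: float | None = None,
) -> np.ndarray:
    """Attachment log-likelihood per edge for one query character."""
    if query_state is None:
        return np.log(Med.sum(axis=1))
    if not (0 <= query_state < model.k):
        raise StateOutOfRangeError(f"query state {query_state} out of range")
    tp = model.pendant_length if pendant_length is None else pendant_length
    col = model.transition(tp)[:, query_state]
    return np.log(Med @ col)
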