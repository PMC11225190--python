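"""Multi-response permutation procedure (MRPP).

MRPP tests whether predefined groups of specimens are more phenotypically
homogeneous than expected by chance. The test statistic is the weighted
mean within-group pairwise distance

    delta = sum_g C_g * xbar_g,   C_g = n_g / N (natural) or 1/G (equal),

compared against its permutation null. The chance-corrected within-group
agreement is A = 1 - delta_obs / delta_expected, where delta_expected is
the overall mean pairwise distance among the grouped specimens (which
equals the mean of delta over all relabelings under either weighting).
A = 1 when items within groups are identical, ~0 at chance, negative when
groups are more heterogeneous than chance. The p-value is a permutation
p-value; when the number of distinct group assignments is small the null
is enumerated exhaustively and p is exact.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chardata import CharacterMatrix
from .errors import MissingDataError
from .scenario import GroupingScenario

EXHAUSTIVE_LIMIT = 10_000


# ---------------------------------------------------------------------------
# Distances with pairwise-complete missing-value handling
# ---------------------------------------------------------------------------

def pairwise_distances(
    matrix: CharacterMatrix,
    metric: str = "euclidean",
    character_subset: frozenset[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Symmetric specimen distance matrix.

    Missing values are handled pairwise-complete: each pair is compared on
    the characters observed in both, and (for euclidean) the summed squared
    difference is rescaled by the fraction of characters observed so that
    sparsely observed pairs are not artificially close. Gower normalizes
    each character by its observed range; Bray-Curtis is the usual ratio on
    shared observed characters.
    """
    m = matrix if character_subset is None else matrix.subset_characters(
        sorted(character_subset)
    )
    X = m.states.astype(float)
    X[m.missing_mask] = np.nan
    n, C = X.shape
    obs = ~np.isnan(X)
    both = obs[:, None, :] & obs[None, :, :]
    n_both = both.sum(axis=2)
    if np.any(n_both[~np.eye(n, dtype=bool)] == 0):
        i, j = np.argwhere((n_both == 0) & ~np.eye(n, dtype=bool))[0]
        raise MissingDataError(
            f"specimens {m.specimen_ids[i]!r} and {m.specimen_ids[j]!r} share "
            "no observed characters"
        )
    diff = X[:, None, :] - X[None, :, :]
    if metric == "euclidean":
        sq = np.where(both, diff**2, 0.0).sum(axis=2)
        D = np.sqrt(sq * C / n_both)
    elif metric == "gower":
        rng = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
        rng[rng == 0] = 1.0  # constant characters contribute 0
        D = np.where(both, np.abs(diff) / rng[None, None, :], 0.0).sum(axis=2) / n_both
    elif metric == "bray_curtis":
        num = np.where(both, np.abs(diff), 0.0).sum(axis=2)
        den = np.where(both, X[:, None, :] + X[None, :, :], 0.0).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(den > 0, num / den, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return D, list(m.specimen_ids)


# ---------------------------------------------------------------------------
# The test
# ---------------------------------------------------------------------------

@dataclass
class MRPPResult:
    scenario: str
    delta_obs: float
    delta_expected: float
    A: float
    p: float
    n_perm: int
    seed: int | None
    exhaustive: bool
    group_sizes: tuple[int, ...]
    degenerate: bool = False  # all distances zero; A undefined (NaN)


def _delta(D: np.ndarray, group_index: list[np.ndarray], coef: np.ndarray) -> float:
    total = 0.0
    for g, idx in enumerate(group_index):
        sub = D[np.ix_(idx, idx)]
        m = len(idx)
        total += coef[g] * sub[np.triu_indices(m, 1)].mean()
    return total


def _assignments(pool: np.ndarray, sizes: list[int]):
    """Yield all distinct assignments of pooled indices to ordered groups."""
    if len(sizes) == 1:
        yield [pool]
        return
    for combo in itertools.combinations(range(len(pool)), sizes[0]):
        first = pool[list(combo)]
        rest = np.delete(pool, list(combo))
        for tail in _assignments(rest, sizes[1:]):
            yield [first] + tail


def mrpp(
    dist: np.ndarray,
    ids: list[str],
    scenario: GroupingScenario,
    n_perm: int = 9999,
    seed: int | None = None,
    weighting: str = "natural",
) -> MRPPResult:
    """Run MRPP for one grouping scenario on a precomputed distance matrix.

    Enumerates the permutation null exhaustively when the number of
    distinct assignments is at most 10,000 (exact p = proportion of
    assignments with delta <= delta_obs); otherwise samples ``n_perm``
    random relabelings and reports p = (1 + #{delta_perm <= delta_obs}) /
    (1 + n_perm).
    """
    index = {s: i for i, s in enumerate(ids)}
    names = sorted(scenario.groups)
    group_index = [
        np.array(sorted(index[s] for s in scenario.groups[g])) for g in names
    ]
    sizes = [len(gi) for gi in group_index]
    N, G = sum(sizes), len(sizes)
    if weighting == "natural":
        coef = np.array(sizes, dtype=float) / N
    elif weighting == "equal":
        coef = np.full(G, 1.0 / G)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    pooled = np.concatenate(group_index)
    sub = dist[np.ix_(pooled, pooled)]
    delta_expected = float(sub[np.triu_indices(N, 1)].mean())
    delta_obs = _delta(dist, group_index, coef)
    if delta_expected == 0.0:
        return MRPPResult(
            scenario.name, delta_obs, 0.0, float("nan"), 1.0, 0, seed, False,
            tuple(sizes), degenerate=True,
        )
    A = 1.0 - delta_obs / delta_expected

    n_total = math.factorial(N)
    for s in sizes:
        n_total //= math.factorial(s)
    if n_total <= EXHAUSTIVE_LIMIT:
        deltas = np.array(
            [
                _delta(dist, assign, coef)
                for assign in _assignments(pooled.copy(), sizes)
            ]
        )
        p = float((deltas <= delta_obs + 1e-12).sum() / len(deltas))
        return MRPPResult(
            scenario.name, delta_obs, delta_expected, A, p, len(deltas), seed,
            True, tuple(sizes),
        )

    tag = zlib.crc32(scenario.name.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, tag] if seed is not None else None
    )
    count = 0
    bounds = np.cumsum(sizes)[:-1]
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        groups = np.split(perm, bounds)
        if _delta(dist, groups, coef) <= delta_obs + 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MRPPResult(
        scenario.name, delta_obs, delta_expected, A, p, n_perm, seed, False,
        tuple(sizes),
    )


def run_scenarios(
    matrix: CharacterMatrix,
    scenarios: list[GroupingScenario],
    metric: str = "euclidean",
    n_perm: int = 9999,
    seed: int | None = None,
    weighting: str = "natural",
) -> pd.DataFrame:
    """One MRPP row per scenario (complete and character-subset variants)."""
    rows = []
    for sc in scenarios:
        sc.validate_against(matrix)
        D, ids = pairwise_distances(matrix, metric, sc.character_subset)
        res = mrpp(D, ids, sc, n_perm=n_perm, seed=seed, weighting=weighting)
        rows.append(
            {
                "scenario": sc.name,
                "groups": " vs ".join(sorted(sc.groups)),
                "character_subset": (
                    "" if sc.character_subset is None
                    else ";".join(sorted(sc.character_subset))
                ),
                "n_specimens": sum(res.group_sizes),
                "delta_obs": res.delta_obs,
                "delta_expected": res.delta_expected,
                "A": res.A,
                "p": res.p,
                "n_perm": res.n_perm,
                "exhaustive": res.exhaustive,
            }
        )
    return pd.DataFrame(rows)
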