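"""Evolutionary placement of phenotype-only queries on the reference tree.

Each query is scored on every edge of the reference tree under weighted
parsimony (total weighted steps of the extended tree, minimized) and
weighted Mk likelihood (total weighted attachment log-likelihood,
maximized). Support for each edge comes from non-parametric bootstrapping
over characters: character columns are resampled with replacement (their
calibrated weights travel with them) and the percentage of replicates in
which an edge is optimal is its bootstrap support. Queries are then
classified against named molecular clades, and placements can be exported
as jplace v3 and CSV classification tables.
"""

from __future__ import annotations

import json
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import WeightVector, character_is_ordered, reference_states
from .chardata import CharacterMatrix
from .errors import MissingDataError, OverlappingCladesError
from .likelihood import MkModel, ml_edge_tables, ml_insertion_logliks
from .parsimony import mp_insertion_scores, sankoff_edge_tables, step_matrix
from .tree import ReferenceTree


@dataclass
class PlacementResult:
    """Per-edge objective and bootstrap support for one query."""

    query_id: str
    criterion: str  # "ML" or "MP"
    per_edge_score: np.ndarray  # (n_edges,) total weighted objective
    best_edge: int
    bootstrap_support: dict[int, int] = field(default_factory=dict)
    n_replicates: int = 0
    seed: int | None = None


@dataclass
class ClassificationRecord:
    """Two-criterion clade assignment for one query."""

    query_id: str
    clade_ML: str = "unsupported"
    BS_ML: int = 0
    clade_MP: str = "unsupported"
    BS_MP: int = 0
    alternatives: list[tuple[str, str, int]] = field(default_factory=list)
    # (criterion, clade, support) triples for secondary clades


class EdgeScorer:
    """Precomputed per-character edge-insertion tables for one tree.

    The per-character tables depend only on the reference data, so a single
    scorer serves every query and every bootstrap replicate. ``criterion``
    is "MP" (scores are total steps, lower is better) or "ML" (scores are
    attachment log-likelihoods, higher is better).
    """

    def __init__(
        self,
        tree: ReferenceTree,
        matrix: CharacterMatrix,
        criterion: str,
        models: dict[str, MkModel] | None = None,
        pendant_length: float | None = None,
    ):
        if criterion not in ("ML", "MP"):
            raise ValueError(f"unknown criterion {criterion!r}")
        self.tree = tree
        self.criterion = criterion
        self.char_ids = matrix.character_ids
        self.specs = list(matrix.specs)
        self.pendant_length = (
            tree.mean_pendant_length() if pendant_length is None else pendant_length
        )
        labels = tree.terminal_labels
        self._tables = []
        for j, spec in enumerate(matrix.specs):
            states = reference_states(matrix, j, labels)
            if criterion == "MP":
                S = step_matrix(spec.n_states, character_is_ordered(spec.kind))
                self._tables.append((sankoff_edge_tables(tree, states, S), S))
            else:
                if models is None or spec.id not in models:
                    raise ValueError("ML scoring requires fitted per-character models")
                m = models[spec.id]
                model = MkModel(m.k, m.beta, self.pendant_length)
                self._tables.append((ml_edge_tables(tree, states, model), model))

    @property
    def n_edges(self) -> int:
        return self.tree.n_edges

    def query_score_matrix(self, query_states: list[int | None]) -> np.ndarray:
        """Per-character, per-edge objective matrix (C x E).

        Characters missing in the query contribute an edge-constant row
        (the base-tree objective), i.e. nothing to the ranking.
        """
        if len(query_states) != len(self._tables):
            raise ValueError("query state vector length mismatch")
        rows = np.empty((len(self._tables), self.n_edges))
        for j, q in enumerate(query_states):
            if self.criterion == "MP":
                M, S = self._tables[j]
                rows[j] = mp_insertion_scores(M, S, q)
            else:
                Med, model = self._tables[j]
                rows[j] = ml_insertion_logliks(Med, model, q)
        return rows


def query_states_from_matrix(
    matrix: CharacterMatrix, specimen_id: str
) -> list[int | None]:
    i = matrix.row(specimen_id)
    return [
        None if matrix.missing_mask[i, j] else int(matrix.states[i, j])
        for j in range(matrix.n_characters)
    ]


def _best_edge(total: np.ndarray, criterion: str) -> int:
    """Optimal edge with deterministic lowest-edge-id tie-breaking."""
    return int(np.argmin(total) if criterion == "MP" else np.argmax(total))


def place_query(
    query_id: str,
    query_states: list[int | None],
    scorer: EdgeScorer,
    weights: WeightVector,
) -> PlacementResult:
    """Score one query on every edge under one criterion."""
    if all(q is None for q in query_states):
        raise MissingDataError(f"query {query_id!r} has no observed characters")
    w = weights.as_array(scorer.char_ids)
    Q = scorer.query_score_matrix(query_states)
    total = w @ Q
    return PlacementResult(
        query_id=query_id,
        criterion=scorer.criterion,
        per_edge_score=total,
        best_edge=_best_edge(total, scorer.criterion),
    )


def _rounded_percent(counts: np.ndarray, n: int) -> dict[int, int]:
    """Integer percentages by largest remainder, summing to exactly 100."""
    raw = 100.0 * counts / n
    base = np.floor(raw).astype(int)
    short = 100 - base.sum()
    order = np.argsort(-(raw - base), kind="stable")  # ties -> lowest edge id
    for e in order[:short]:
        base[e] += 1
    return {int(e): int(v) for e, v in enumerate(base) if v > 0}


def bootstrap_placement(
    query_id: str,
    query_states: list[int | None],
    scorer: EdgeScorer,
    weights: WeightVector,
    n_replicates: int = 100,
    seed: int = 0,
) -> PlacementResult:
    """Character-bootstrap placement support.

    One named generator is seeded per (query, criterion) from the master
    seed, so supports are reproducible independent of run order.
    """
    result = place_query(query_id, query_states, scorer, weights)
    w = weights.as_array(scorer.char_ids)
    Q = scorer.query_score_matrix(query_states)
    C = Q.shape[0]
    tag = zlib.crc32(f"{query_id}|{scorer.criterion}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, tag])
    counts = np.zeros(scorer.n_edges, dtype=int)
    wQ = w[:, None] * Q
    for _ in range(n_replicates):
        idx = rng.integers(0, C, size=C)
        total = wQ[idx].sum(axis=0)
        counts[_best_edge(total, scorer.criterion)] += 1
    result.bootstrap_support = _rounded_percent(counts, n_replicates)
    result.n_replicates = n_replicates
    result.seed = int(seed)
    return result


# ---------------------------------------------------------------------------
# Classification against named clades
# ---------------------------------------------------------------------------

def clade_edges(tree: ReferenceTree) -> dict[str, set[int]]:
    """Edges whose distal subtree lies fully inside each named clade."""
    tree.validate_clade_map()
    out: dict[str, set[int]] = {}
    for name, members in tree.clade_map.items():
        out[name] = {
            e
            for e in range(tree.n_edges)
            if tree.edge_subtree_labels(e) <= members
        }
    return out


def clade_support(
    placement: PlacementResult, clade_edge_sets: dict[str, set[int]]
) -> dict[str, int]:
    """Summed bootstrap support per clade."""
    return {
        name: sum(
            bs for e, bs in placement.bootstrap_support.items() if e in edges
        )
        for name, edges in clade_edge_sets.items()
    }


def classify(
    placements: dict[str, PlacementResult],
    tree: ReferenceTree,
    threshold: int = 70,
    alternative_threshold: int = 5,
) -> ClassificationRecord:
    """Assign one query to clades under each criterion.

    A query is assigned to the clade with maximal summed support when that
    support reaches the threshold, otherwise marked "unsupported".
    Secondary clades at or above ``alternative_threshold`` are listed as
    alternatives, so queries binned into several clades stay visible.
    """
    edge_sets = clade_edges(tree)
    qids = {p.query_id for p in placements.values()}
    if len(qids) != 1:
        raise ValueError("classify expects placements of a single query")
    rec = ClassificationRecord(query_id=qids.pop())
    for criterion, placement in placements.items():
        supports = clade_support(placement, edge_sets)
        ranked = sorted(supports.items(), key=lambda kv: (-kv[1], kv[0]))
        best_name, best_bs = ranked[0] if ranked else ("unsupported", 0)
        assigned = best_name if best_bs >= threshold else "unsupported"
        if criterion == "ML":
            rec.clade_ML, rec.BS_ML = assigned, best_bs
        else:
            rec.clade_MP, rec.BS_MP = assigned, best_bs
        for name, bs in ranked[1:]:
            if bs >= alternative_threshold:
                rec.alternatives.append((criterion, name, bs))
    return rec


def extended_clades(
    records: list[ClassificationRecord], tree: ReferenceTree, criterion: str
) -> dict[str, frozenset[str]]:
    """Molecular clades augmented with the queries binned into them."""
    out = {name: set(members) for name, members in tree.clade_map.items()}
    for rec in records:
        clade = rec.clade_ML if criterion == "ML" else rec.clade_MP
        if clade != "unsupported":
            out[clade].add(rec.query_id)
    return {k: frozenset(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# jplace v3 and classification CSV
# ---------------------------------------------------------------------------

def _newick_with_edge_numbers(tree: ReferenceTree) -> str:
    def render(node: int) -> str:
        if tree.is_leaf(node):
            body = tree.leaf_label[node]
        else:
            body = "(" + ",".join(render(c) for c in tree.children[node]) + ")"
        if node == tree.root:
            return body
        return f"{body}:{tree.blen[node]:.12g}{{{tree.edge_of_node[node]}}}"

    return render(tree.root) + ";"


def write_jplace(
    placements: list[PlacementResult], tree: ReferenceTree, path: str | Path
) -> None:
    """Serialize placements as jplace version 3."""
    doc = {
        "version": 3,
        "tree": _newick_with_edge_numbers(tree),
        "fields": ["edge_num", "like_weight_ratio"],
        "placements": [
            {
                "p": [
                    [int(e), bs / 100.0]
                    for e, bs in sorted(
                        p.bootstrap_support.items(), key=lambda kv: (-kv[1], kv[0])
                    )
                ],
                "n": [p.query_id],
            }
            for p in placements
        ],
        "metadata": {"invocation": "phenobin placement", "criterion": (
            placements[0].criterion if placements else ""
        )},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_jplace(path: str | Path) -> dict[str, dict[int, int]]:
    """Recover per-query edge supports (percent) from a jplace file."""
    doc = json.loads(Path(path).read_text())
    out = {}
    for p in doc["placements"]:
        name = p["n"][0]
        out[name] = {
            int(edge): int(round(100 * lwr)) for edge, lwr, *_ in p["p"]
        }
    return out


def classification_table(records: list[ClassificationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        alts = ";".join(f"{cr}:{cl}:{bs}" for cr, cl, bs in r.alternatives)
        rows.append(
            {
                "query": r.query_id,
                "clade_ML": r.clade_ML,
                "BS_ML": r.BS_ML,
                "clade_MP": r.clade_MP,
                "BS_MP": r.BS_MP,
                "alternatives": alts,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["query", "clade_ML", "BS_ML", "clade_MP", "BS_MP", "alternatives"],
    )


def write_classification_csv(
    records: list[ClassificationRecord], path: str | Path
) -> None:
    classification_table(records).to_csv(path, index=False)
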