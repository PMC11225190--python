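"""Character-weight calibration against the molecular reference tree.

Each phenotype character earns an integer weight in [0, 100] measuring how
reliably it recovers the known positions of the reference taxa: every
reference terminal is pruned in turn and re-inserted on every edge using
that character alone; the character supports the placement when the true
attachment edge attains the optimal insertion objective (minimal added
steps under MP, maximal attachment log-likelihood under the Mk model for
ML). The weight is 100 * supporting / informative placements, rounded.
Characters invariant across the reference taxa are uninformative by
construction and receive weight 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chardata import CharacterMatrix
from .errors import LabelMismatchError
from .likelihood import MkModel, fit_beta, ml_edge_tables, ml_insertion_logliks
from .parsimony import mp_insertion_scores, sankoff_edge_tables, step_matrix
from .tree import ReferenceTree

# MP scores are integers, so any positive tolerance below 1 recognizes exact
# ties. ML attachment log-likelihoods within one same-state region of the
# tree differ only by O(beta * branch length) surface roughness (~1e-4),
# while edges in the wrong state region are worse by O(1) log units; the ML
# tie window sits between those scales so that region-level ties count as
# support, mirroring the exact-tie semantics of parsimony.
ML_TIE_TOL = 1e-2
MP_TIE_TOL = 1e-9


@dataclass
class WeightVector:
    """Calibrated per-character weights under one criterion."""

    criterion: str  # "ML" or "MP"
    weights: dict[str, int]
    support_counts: dict[str, tuple[int, int]]  # char -> (n_supporting, n_informative)
    significance_threshold: int = 70

    def as_array(self, char_ids: list[str]) -> np.ndarray:
        return np.array([self.weights[c] for c in char_ids], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "character": c,
                f"weight_{self.criterion}": w,
                "n_supporting": self.support_counts[c][0],
                "n_informative": self.support_counts[c][1],
            }
            for c, w in self.weights.items()
        ]
        return pd.DataFrame(rows)


def character_is_ordered(kind: str) -> bool:
    """Ordered steps for multistate and gap-coded characters; binary is
    equivalent under both conventions."""
    return kind in ("ordered_multistate", "continuous")


def reference_states(
    matrix: CharacterMatrix, char_index: int, labels: list[str]
) -> dict[str, int | None]:
    """Terminal label -> coded state (None when missing) for one character.

    Tree terminals are matched to specimens by specimen id.
    """
    out: dict[str, int | None] = {}
    for lab in labels:
        i = matrix.row(lab)
        out[lab] = (
            None
            if matrix.missing_mask[i, char_index]
            else int(matrix.states[i, char_index])
        )
    return out


def check_tree_matrix_correspondence(
    matrix: CharacterMatrix, tree: ReferenceTree
) -> None:
    missing = [lab for lab in tree.terminal_labels if lab not in matrix.specimen_ids]
    if missing:
        raise LabelMismatchError(
            f"tree terminals without a matrix row: {sorted(missing)}"
        )


def fit_character_models(
    matrix: CharacterMatrix,
    tree: ReferenceTree,
    pendant_length: float | None = None,
) -> dict[str, MkModel]:
    """Per-character Mk rate fitted on the intact reference tree.

    The fitted rates are reused unchanged during leave-one-out calibration
    and query placement; the pendant length defaults to the tree's mean
    pendant branch length.
    """
    check_tree_matrix_correspondence(matrix, tree)
    tp = tree.mean_pendant_length() if pendant_length is None else pendant_length
    labels = tree.terminal_labels
    models = {}
    for j, spec in enumerate(matrix.specs):
        states = reference_states(matrix, j, labels)
        observed = {s for s in states.values() if s is not None}
        if len(observed) < 2:
            # invariant or unobserved: rate pinned at the lower bound
            models[spec.id] = MkModel(spec.n_states, 1e-4, tp)
        else:
            models[spec.id] = fit_beta(tree, states, spec.n_states, tp)
    return models


def calibrate_weights(
    matrix: CharacterMatrix,
    tree: ReferenceTree,
    criterion: str,
    models: dict[str, MkModel] | None = None,
    pendant_length: float | None = None,
    significance_threshold: int = 70,
) -> WeightVector:
    """Leave-one-out self-placement weight calibration.

    For every reference terminal r and every character observed in r, the
    terminal is pruned and its state scored on every edge of the pruned
    tree; the placement is *informative* when the character still varies
    among the remaining terminals, and *supporting* when the true edge
    attains the optimum (exact for MP, within 1e-9 for ML).
    """
    if criterion not in ("ML", "MP"):
        raise ValueError(f"unknown criterion {criterion!r}")
    check_tree_matrix_correspondence(matrix, tree)
    if tree.n_terminals < 4:
        raise LabelMismatchError("calibration needs >= 4 reference terminals")
    if criterion == "ML" and models is None:
        models = fit_character_models(matrix, tree, pendant_length)
    tp = tree.mean_pendant_length() if pendant_length is None else pendant_length

    supporting = {s.id: 0 for s in matrix.specs}
    informative = {s.id: 0 for s in matrix.specs}
    labels_all = tree.terminal_labels
    invariant = {}
    for j, spec in enumerate(matrix.specs):
        obs = {
            s for s in reference_states(matrix, j, labels_all).values()
            if s is not None
        }
        invariant[spec.id] = len(obs) < 2
    for r in tree.terminal_labels:
        pruned, true_edges = tree.prune_terminal(r)
        remaining = pruned.terminal_labels
        for j, spec in enumerate(matrix.specs):
            i = matrix.row(r)
            if matrix.missing_mask[i, j]:
                continue
            q = int(matrix.states[i, j])
            states = reference_states(matrix, j, remaining)
            observed = {s for s in states.values() if s is not None}
            if len(observed) < 2:
                continue  # uninformative for this pruning
            if criterion == "MP":
                S = step_matrix(spec.n_states, character_is_ordered(spec.kind))
                scores = mp_insertion_scores(
                    sankoff_edge_tables(pruned, states, S), S, q
                )
                if scores.max() - scores.min() <= MP_TIE_TOL:
                    continue  # flat objective (e.g. autapomorphy): no signal
                best = scores.min()
                hit = any(scores[e] <= best + MP_TIE_TOL for e in true_edges)
            else:
                model = models[spec.id]
                model = MkModel(model.k, model.beta, tp)
                lnl = ml_insertion_logliks(
                    ml_edge_tables(pruned, states, model), model, q
                )
                if lnl.max() - lnl.min() <= ML_TIE_TOL:
                    continue  # numerically flat (saturated rate): no signal
                best = lnl.max()
                hit = any(lnl[e] >= best - ML_TIE_TOL for e in true_edges)
            informative[spec.id] += 1
            if hit:
                supporting[spec.id] += 1

    weights = {}
    counts = {}
    for spec in matrix.specs:
        sup, inf = supporting[spec.id], informative[spec.id]
        if invariant[spec.id]:
            # invariant across reference taxa: conventionally fully reliable
            weights[spec.id] = 100
        elif inf == 0:
            # variable but never informative (e.g. flat objectives throughout)
            weights[spec.id] = 0
        else:
            weights[spec.id] = int(np.floor(100.0 * sup / inf + 0.5))
        counts[spec.id] = (sup, inf)
    return WeightVector(criterion, weights, counts, significance_threshold)


def read_weight_table(path) -> dict[str, "WeightVector"]:
    """Load per-criterion WeightVectors back from a weights CSV."""
    df = pd.read_csv(path)
    out = {}
    for criterion in ("ML", "MP"):
        col = f"weight_{criterion}"
        if col not in df.columns:
            continue
        weights = dict(zip(df["character"].astype(str), df[col].astype(int)))
        sup_col = f"n_supporting_{criterion}"
        inf_col = f"n_informative_{criterion}"
        counts = {
            str(c): (int(s), int(i))
            for c, s, i in zip(
                df["character"],
                df.get(sup_col, pd.Series(0, index=df.index)),
                df.get(inf_col, pd.Series(0, index=df.index)),
            )
        }
        out[criterion] = WeightVector(criterion, weights, counts)
    return out


def weight_table(
    vectors: list[WeightVector], matrix: CharacterMatrix
) -> pd.DataFrame:
    """Merged weight table (one weight column per criterion)."""
    df = pd.DataFrame(
        {
            "character": [s.id for s in matrix.specs],
            "label": [s.label for s in matrix.specs],
            "kind": [s.kind for s in matrix.specs],
            "category": [s.category for s in matrix.specs],
        }
    )
    for wv in vectors:
        df[f"weight_{wv.criterion}"] = [wv.weights[s.id] for s in matrix.specs]
        df[f"n_supporting_{wv.criterion}"] = [
            wv.support_counts[s.id][0] for s in matrix.specs
        ]
        df[f"n_informative_{wv.criterion}"] = [
            wv.support_counts[s.id][1] for s in matrix.specs
        ]
    return df
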