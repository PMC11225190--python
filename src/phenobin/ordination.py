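"""Correlation-matrix PCA with taxon-mean imputation and a randomization
test of axis significance.

Missing cells are interpolated from conspecific specimens (type material
first when flagged) before ordination; specimens with unresolvable cells
are dropped or rejected per policy. PCA uses correlation to compute the
cross-products matrix, so eigenvalues sum to the number of variables;
axis significance comes from independently permuting values within every
column and comparing randomized eigenvalues with the observed ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chardata import CharacterMatrix
from .errors import ImputationError


@dataclass
class ImputationReport:
    filled: pd.DataFrame  # one row per filled cell
    dropped_specimens: list[str]


def impute_missing(
    matrix: CharacterMatrix,
    policy: str = "taxon_mean",
    unresolvable: str = "drop_specimen",
) -> tuple[np.ndarray, list[str], ImputationReport]:
    """Complete the coded matrix for ordination.

    ``taxon_mean`` fills each missing cell with the mean coded state of
    same-taxon specimens in which the character was observed, preferring
    specimens flagged as type material; cells with no conspecific donor
    either drop the specimen (mirroring the exclusion of sterile specimens
    from ordination) or raise, per ``unresolvable``. ``drop_specimen``
    simply removes every specimen with any missing cell.

    Returns the completed (float) matrix, the retained specimen ids, and a
    report listing every filled cell.
    """
    X = matrix.states.astype(float)
    X[matrix.missing_mask] = np.nan
    taxa = np.asarray(matrix.taxon_labels)
    keep = np.ones(matrix.n_specimens, dtype=bool)
    filled_rows = []
    if policy == "drop_specimen":
        keep = ~matrix.missing_mask.any(axis=1)
    elif policy == "taxon_mean":
        for i in range(matrix.n_specimens):
            for j in np.where(matrix.missing_mask[i])[0]:
                same = (taxa == taxa[i]) & ~matrix.missing_mask[:, j]
                same[i] = False
                donors = np.where(same)[0]
                if matrix.is_type is not None:
                    typed = donors[matrix.is_type[donors]]
                    if typed.size:
                        donors = typed
                if donors.size == 0:
                    if unresolvable == "drop_specimen":
                        keep[i] = False
                        break
                    raise ImputationError(
                        f"specimen {matrix.specimen_ids[i]!r}, character "
                        f"{matrix.specs[j].id!r}: no same-taxon donor"
                    )
                value = float(matrix.states[donors, j].mean())
                X[i, j] = value
                filled_rows.append(
                    {
                        "specimen": matrix.specimen_ids[i],
                        "character": matrix.specs[j].id,
                        "value": value,
                        "n_donors": int(donors.size),
                    }
                )
    else:
        raise ValueError(f"unknown imputation policy {policy!r}")
    ids = [s for s, k in zip(matrix.specimen_ids, keep) if k]
    report = ImputationReport(
        filled=pd.DataFrame(
            filled_rows, columns=["specimen", "character", "value", "n_donors"]
        ),
        dropped_specimens=[s for s, k in zip(matrix.specimen_ids, keep) if not k],
    )
    return X[keep], ids, report


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # non-increasing
    scores: np.ndarray  # specimen x axis
    loadings: np.ndarray  # variable x axis (unit eigenvectors)
    variance_explained: np.ndarray
    variable_names: list[str]
    specimen_ids: list[str]
    dropped_variables: list[str] = field(default_factory=list)
    axis_p: np.ndarray | None = None
    n_rand: int = 0
    seed: int | None = None


def _correlation_eigen(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    R = np.corrcoef(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    return vals, vecs[:, order]


def pca(
    X: np.ndarray,
    variable_names: list[str] | None = None,
    specimen_ids: list[str] | None = None,
) -> PCAResult:
    """Eigendecomposition of the variable correlation matrix.

    Zero-variance variables are dropped with a warning (their correlation
    is undefined). Axis signs follow the convention that the
    largest-magnitude loading on each axis is positive, so results are
    fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    variable_names = variable_names or [f"v{j}" for j in range(p)]
    specimen_ids = specimen_ids or [f"s{i}" for i in range(n)]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [v for v, k in zip(variable_names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance variables: {dropped}")
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant variables")
    Xk = X[:, keep]
    vals, vecs = _correlation_eigen(Xk)
    # sign convention: largest-magnitude loading positive per axis
    for a in range(vecs.shape[1]):
        jmax = int(np.argmax(np.abs(vecs[:, a])))
        if vecs[jmax, a] < 0:
            vecs[:, a] = -vecs[:, a]
    Z = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0, ddof=1)
    return PCAResult(
        eigenvalues=vals,
        scores=Z @ vecs,
        loadings=vecs,
        variance_explained=vals / vals.sum(),
        variable_names=[v for v, k in zip(variable_names, keep) if k],
        specimen_ids=list(specimen_ids),
        dropped_variables=dropped,
    )


def pca_randomization(
    X: np.ndarray,
    result: PCAResult | None = None,
    n_rand: int = 999,
    seed: int | None = None,
    variable_names: list[str] | None = None,
) -> np.ndarray:
    """Per-axis randomization p-values.

    Each replicate independently permutes the values within every column,
    destroying inter-variable correlation while keeping marginals; axis k
    is significant when few randomized k-th eigenvalues reach the observed
    one: p_k = (1 + #{lambda*_k >= lambda_k}) / (1 + n_rand).
    """
    X = np.asarray(X, dtype=float)
    if result is None:
        result = pca(X, variable_names)
    keep = [j for j, v in enumerate(variable_names or result.variable_names)
            if v in set(result.variable_names)] if variable_names else None
    Xk = X[:, keep] if keep is not None else X[:, X.std(axis=0, ddof=1) > 0]
    rng = np.random.default_rng(
        None if seed is None else int(seed) & 0x7FFFFFFF
    )
    obs = result.eigenvalues
    exceed = np.zeros_like(obs)
    n, p = Xk.shape
    for _ in range(n_rand):
        Xr = np.column_stack([rng.permutation(Xk[:, j]) for j in range(p)])
        vals, _ = _correlation_eigen(Xr)
        exceed += vals >= obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_rand)
    result.axis_p = pvals
    result.n_rand = n_rand
    result.seed = seed
    return pvals
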