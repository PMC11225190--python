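"""End-to-end orchestration: calibrate, bin, extend clades, MRPP, PCA.

``run_pipeline`` drives the whole analysis from one configuration mapping
and writes a self-describing report bundle: calibrated weight table,
jplace placements and classification table per criterion, extended-clade
definitions, MRPP results, PCA outputs, and a run log carrying the master
seed, a configuration hash and package versions. Every stage failure is
re-raised as a stage-named error with earlier outputs preserved.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import calibrate_weights, fit_character_models, weight_table
from .chardata import CharacterMatrix, read_character_matrix, read_character_specs
from .errors import PipelineStageError
from .mrpp import run_scenarios
from .ordination import impute_missing, pca, pca_randomization
from .placement import (
    EdgeScorer,
    bootstrap_placement,
    classify,
    extended_clades,
    query_states_from_matrix,
    write_classification_csv,
    write_jplace,
)
from .scenario import read_scenarios
from .tree import read_tree

DEFAULTS = {
    "criteria": ["ML", "MP"],
    "bootstrap_replicates": 100,
    "support_threshold": 70,
    "alternative_threshold": 5,
    "pendant_length": None,
    "polytomy_policy": "reject",
    "mrpp": {"metric": "euclidean", "n_perm": 9999, "weighting": "natural"},
    "pca": {"n_rand": 999, "imputation": "taxon_mean", "unresolvable": "drop_specimen"},
    "stages": ["calibrate", "place", "mrpp", "pca"],
    "seed": 0,
}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return merge_defaults(cfg)


def merge_defaults(cfg: dict) -> dict:
    out = dict(DEFAULTS)
    for key, value in cfg.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = {**out[key], **value}
        else:
            out[key] = value
    return out


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(
    config: dict,
    output_dir: str | Path,
    matrix: CharacterMatrix | None = None,
    tree=None,
) -> dict[str, Path]:
    """Run the configured stages and write the report bundle.

    ``matrix``/``tree`` may be passed in memory (e.g. from the simulator);
    otherwise they are read from the paths in ``config``. Returns a mapping
    of artifact names to written paths. Deterministic given the seed.
    """
    cfg = merge_defaults(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artifacts: dict[str, Path] = {}

    def stage(name: str):
        if name not in cfg["stages"]:
            return False
        return True

    try:
        if matrix is None:
            specs = (
                read_character_specs(cfg["specs"]) if cfg.get("specs") else None
            )
            matrix = read_character_matrix(cfg["matrix"], specs=specs)
        if tree is None:
            clade_map = {
                name: frozenset(members)
                for name, members in (cfg.get("clades") or {}).items()
            }
            tree = read_tree(
                cfg["tree"], cfg["polytomy_policy"], clade_map or None
            )
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("load", str(exc)) from exc

    reference = matrix.subset_specimens(
        [s for s, r in zip(matrix.specimen_ids, matrix.is_reference) if r]
    )
    query_ids = [
        s for s, r in zip(matrix.specimen_ids, matrix.is_reference) if not r
    ]

    weight_vectors = {}
    models = None
    if stage("calibrate"):
        try:
            if "ML" in cfg["criteria"]:
                models = fit_character_models(
                    reference, tree, cfg["pendant_length"]
                )
            for criterion in cfg["criteria"]:
                weight_vectors[criterion] = calibrate_weights(
                    reference, tree, criterion, models=models,
                    pendant_length=cfg["pendant_length"],
                    significance_threshold=cfg["support_threshold"],
                )
            path = out / "weights.csv"
            weight_table(list(weight_vectors.values()), reference).to_csv(
                path, index=False
            )
            artifacts["weights"] = path
        except Exception as exc:
            raise PipelineStageError("calibrate", str(exc)) from exc

    records = []
    if stage("place") and query_ids:
        try:
            if not weight_vectors:
                raise ValueError(
                    "placement requires calibrated weights: run the "
                    "'calibrate' stage (or `phenobin calibrate`) first"
                )
            per_query: dict[str, dict] = {q: {} for q in query_ids}
            for criterion in cfg["criteria"]:
                scorer = EdgeScorer(
                    tree, reference, criterion, models=models,
                    pendant_length=cfg["pendant_length"],
                )
                placements = []
                for q in query_ids:
                    res = bootstrap_placement(
                        q,
                        query_states_from_matrix(matrix, q),
                        scorer,
                        weight_vectors[criterion],
                        n_replicates=int(cfg["bootstrap_replicates"]),
                        seed=seed,
                    )
                    placements.append(res)
                    per_query[q][criterion] = res
                path = out / f"placements_{criterion}.jplace"
                write_jplace(placements, tree, path)
                artifacts[f"placements_{criterion}"] = path
            for q in query_ids:
                records.append(
                    classify(
                        per_query[q], tree,
                        threshold=int(cfg["support_threshold"]),
                        alternative_threshold=int(cfg["alternative_threshold"]),
                    )
                )
            path = out / "classification.csv"
            write_classification_csv(records, path)
            artifacts["classification"] = path
            ext = {
                criterion: {
                    name: sorted(members)
                    for name, members in extended_clades(
                        records, tree, criterion
                    ).items()
                }
                for criterion in cfg["criteria"]
            }
            path = out / "extended_clades.json"
            path.write_text(json.dumps(ext, indent=1))
            artifacts["extended_clades"] = path
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("place", str(exc)) from exc

    if stage("mrpp") and cfg.get("scenarios"):
        try:
            scenarios = (
                read_scenarios(cfg["scenarios"])
                if isinstance(cfg["scenarios"], (str, Path))
                else cfg["scenarios"]
            )
            table = run_scenarios(
                matrix, scenarios,
                metric=cfg["mrpp"]["metric"],
                n_perm=int(cfg["mrpp"]["n_perm"]),
                seed=seed,
                weighting=cfg["mrpp"]["weighting"],
            )
            path = out / "mrpp.csv"
            table.to_csv(path, index=False)
            artifacts["mrpp"] = path
        except Exception as exc:
            raise PipelineStageError("mrpp", str(exc)) from exc

    if stage("pca"):
        try:
            X, ids, report = impute_missing(
                matrix,
                policy=cfg["pca"]["imputation"],
                unresolvable=cfg["pca"]["unresolvable"],
            )
            result = pca(X, matrix.character_ids, ids)
            pca_randomization(
                X[:, [matrix.character_ids.index(v) for v in result.variable_names]],
                result, n_rand=int(cfg["pca"]["n_rand"]), seed=seed,
            )
            pd.DataFrame(
                result.scores,
                index=ids,
                columns=[f"axis{a + 1}" for a in range(result.scores.shape[1])],
            ).to_csv(out / "pca_scores.csv")
            pd.DataFrame(
                result.loadings,
                index=result.variable_names,
                columns=[f"axis{a + 1}" for a in range(result.loadings.shape[1])],
            ).to_csv(out / "pca_loadings.csv")
            pd.DataFrame(
                {
                    "eigenvalue": result.eigenvalues,
                    "variance_explained": result.variance_explained,
                    "p": result.axis_p,
                }
            ).to_csv(out / "pca_eigenvalues.csv", index_label="axis")
            for name in ("pca_scores", "pca_loadings", "pca_eigenvalues"):
                artifacts[name] = out / f"{name}.csv"
            if len(report.filled):
                report.filled.to_csv(out / "pca_imputation_report.csv", index=False)
                artifacts["pca_imputation_report"] = out / "pca_imputation_report.csv"
        except Exception as exc:
            raise PipelineStageError("pca", str(exc)) from exc

    log = {
        "package": "phenobin",
        "version": __version__,
        "numpy": np.__version__,
        "python": platform.python_version(),
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "config": {k: v for k, v in cfg.items() if not isinstance(v, (bytes,))},
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    artifacts["run_log"] = out / "run_log.json"
    return artifacts
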