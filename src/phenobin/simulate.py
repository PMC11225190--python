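"""Synthetic data with known truth for every pipeline stage.

The generator produces (i) an ultrametric Yule reference tree with named
clades, (ii) a clade-structured character matrix mixing slowly evolving
diagnostic characters with fast, homoplastic ones (discrete characters by
Mk simulation root-to-tips; morphometric characters by Brownian motion
followed by gap coding), with blockwise "sterile specimen" missingness on
apothecia-like character blocks, and (iii) phenotype-only queries evolved
one extra Mk/Brownian step along a pendant branch from a member of a known
source clade. Everything is deterministic under the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chardata import CharacterMatrix, CharacterSpec, code_continuous
from .likelihood import MkModel
from .tree import ReferenceTree


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic test bed.

    Defaults mirror the structure of the empirical setting: a few dozen
    reference taxa, characters split between diagnostic (low rate 0.05)
    and homoplastic (high rate 1.0) halves, mostly binary states with some
    ordered multistate, and a sterile-specimen pattern in which an
    apothecial character block (30% of characters) is entirely missing for
    a specimen with probability 0.3.
    """

    n_reference: int = 24
    tree_model: str = "yule"
    birth_rate: float = 1.0
    n_characters: int = 60
    fraction_diagnostic: float = 0.5
    rate_diagnostic: float = 0.05
    rate_homoplastic: float = 1.0
    n_states_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.5, 3: 0.3, 4: 0.2}
    )
    fraction_continuous: float = 0.0
    continuous_n_states: int = 3
    category_fractions: dict[str, float] = field(
        default_factory=lambda: {"thallus": 0.7, "apothecia": 0.3}
    )
    missing_block: tuple[tuple[str, float], ...] = (("apothecia", 0.3),)
    n_queries_per_clade: int = 2
    query_pendant_length: float | None = None
    seed: int = 0

    def __post_init__(self):
        for f in (self.fraction_diagnostic, self.fraction_continuous):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.rate_diagnostic <= 0 or self.rate_homoplastic <= 0:
            raise ValueError("rates must be positive")
        if self.rate_diagnostic >= self.rate_homoplastic:
            raise ValueError("rate_diagnostic must be < rate_homoplastic")
        if self.n_reference < 4:
            raise ValueError("n_reference must be >= 4")
        if self.tree_model != "yule":
            raise ValueError(f"unknown tree model {self.tree_model!r}")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside the generated data."""

    tree: ReferenceTree
    char_kind: dict[str, str]
    char_rate: dict[str, float]
    char_k: dict[str, int]
    char_breaks: dict[str, tuple[float, ...]]  # continuous characters only
    raw_continuous: dict[str, dict[str, float]]  # char -> label -> BM value
    query_source: dict[str, str] = field(default_factory=dict)
    injected_missing: dict[str, np.ndarray] = field(default_factory=dict)


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


def simulate_tree(config: SimulationConfig) -> ReferenceTree:
    """Ultrametric Yule tree with depth-2 clades named.

    Lineages split at rate ``birth_rate`` each; branch lengths are in
    expected-substitution units (clock rate 1). Every node at topological
    depth 2 with at least two terminals becomes a named clade
    ("cladeA", "cladeB", ...).
    """
    rng = _rng(config.seed, 1)
    n = config.n_reference
    parent = [-1, 0, 0]
    blen = [0.0, 0.0, 0.0]
    children: list[list[int]] = [[1, 2], [], []]
    active = [1, 2]
    while len(active) < n:
        k = len(active)
        dt = rng.exponential(1.0 / (k * config.birth_rate))
        for v in active:
            blen[v] += dt
        split = active.pop(int(rng.integers(k)))
        for _ in range(2):
            parent.append(split)
            blen.append(0.0)
            children.append([])
            children[split].append(len(parent) - 1)
            active.append(len(parent) - 1)
    dt = rng.exponential(1.0 / (n * config.birth_rate))
    for v in active:
        blen[v] += dt
    width = len(str(n))
    leaf_label = {v: f"T{i + 1:0{width}d}" for i, v in enumerate(sorted(active))}
    tree = ReferenceTree(
        np.array(parent), children, np.array(blen), leaf_label
    )
    # name depth-2 clades
    depth = {tree.root: 0}
    clade_map = {}
    letter = 0
    for v in reversed(tree.postorder):
        if v != tree.root:
            depth[v] = depth[int(tree.parent[v])] + 1
    for v in reversed(tree.postorder):  # pre-order: deterministic naming
        if depth[v] == 2 and not tree.is_leaf(v):
            members = tree.edge_subtree_labels(tree.edge_of_node[v])
            if len(members) >= 2:
                clade_map[f"clade{chr(ord('A') + letter)}"] = members
                letter += 1
    return ReferenceTree(
        np.array(parent), children, np.array(blen), leaf_label, clade_map
    )


def _char_plan(config: SimulationConfig, rng: np.random.Generator):
    """Per-character (kind, rate_class, k, category) assignment."""
    n = config.n_characters
    n_cont = int(round(config.fraction_continuous * n))
    n_disc = n - n_cont
    n_diag = int(round(config.fraction_diagnostic * n_disc))
    ks = sorted(config.n_states_distribution)
    probs = np.array([config.n_states_distribution[k] for k in ks], dtype=float)
    probs /= probs.sum()
    cat_names = list(config.category_fractions)
    cat_counts = [int(round(config.category_fractions[c] * n)) for c in cat_names]
    cat_counts[-1] = n - sum(cat_counts[:-1])
    categories = [c for c, m in zip(cat_names, cat_counts) for _ in range(m)]
    plan = []
    for j in range(n):
        if j < n_cont:
            kind, k = "continuous", config.continuous_n_states
            rate = config.rate_diagnostic  # BM is tree-faithful by construction
        else:
            jd = j - n_cont
            kind = "binary"
            k = int(rng.choice(ks, p=probs))
            if k > 2:
                kind = "ordered_multistate"
            rate = config.rate_diagnostic if jd < n_diag else config.rate_homoplastic
        plan.append((kind, rate, k, categories[j]))
    return plan


def _evolve_discrete(
    tree: ReferenceTree, k: int, rate: float, rng: np.random.Generator
) -> dict[int, int]:
    """Mk simulation root-to-tips; returns state per node."""
    model = MkModel(k, rate)
    states = {tree.root: int(rng.integers(k))}
    for v in reversed(tree.postorder):
        if v == tree.root:
            continue
        P = model.transition(float(tree.blen[v]))
        states[v] = int(rng.choice(k, p=P[states[int(tree.parent[v])]]))
    return states


def _evolve_brownian(
    tree: ReferenceTree, rng: np.random.Generator
) -> dict[int, float]:
    """Unit-variance Brownian motion root-to-tips."""
    values = {tree.root: 0.0}
    for v in reversed(tree.postorder):
        if v == tree.root:
            continue
        t = float(tree.blen[v])
        values[v] = values[int(tree.parent[v])] + rng.normal(0.0, np.sqrt(max(t, 0.0)))
    return values


def simulate_characters(
    tree: ReferenceTree, config: SimulationConfig
) -> tuple[CharacterMatrix, SimulationTruth]:
    """Reference character matrix plus recorded truth."""
    rng = _rng(config.seed, 2)
    plan = _char_plan(config, rng)
    labels = tree.terminal_labels
    n = len(labels)
    specs, cols, kinds, rates, kmap, breaks_map, raw_map = [], [], {}, {}, {}, {}, {}
    for j, (kind, rate, k, category) in enumerate(plan):
        cid = f"c{j + 1:03d}"
        spec = CharacterSpec(
            id=cid, label=f"simulated {kind} character", kind=kind,
            n_states=k, category=category,
        )
        if kind == "continuous":
            node_vals = _evolve_brownian(tree, rng)
            vals = [node_vals[tree.label_to_node[lab]] for lab in labels]
            lo, hi = min(vals), max(vals)
            br = (
                tuple(float(b) for b in lo + (hi - lo) / k * np.arange(1, k))
                if hi > lo
                else None  # degenerate range: automatic coding -> all state 0
            )
            spec = CharacterSpec(
                id=cid, label=spec.label, kind=kind, n_states=k,
                category=category, coding_breaks=br,
            )
            coded = code_continuous(vals, spec)
            cols.append([int(c) for c in coded])
            breaks_map[cid] = br
            raw_map[cid] = dict(zip(labels, map(float, vals)))
        else:
            node_states = _evolve_discrete(tree, k, rate, rng)
            cols.append([node_states[tree.label_to_node[lab]] for lab in labels])
        specs.append(spec)
        kinds[cid], rates[cid], kmap[cid] = kind, rate, k
    states = np.array(cols, dtype=int).T
    missing = _inject_blockwise_missing(config, specs, n, _rng(config.seed, 3))
    matrix = CharacterMatrix(
        specimen_ids=list(labels),
        taxon_labels=list(labels),
        is_reference=np.ones(n, dtype=bool),
        states=states,
        missing_mask=missing,
        specs=specs,
    )
    truth = SimulationTruth(
        tree=tree, char_kind=kinds, char_rate=rates, char_k=kmap,
        char_breaks=breaks_map, raw_continuous=raw_map,
        injected_missing={"reference": missing.copy()},
    )
    return matrix, truth


def _inject_blockwise_missing(
    config: SimulationConfig, specs, n_specimens: int, rng: np.random.Generator
) -> np.ndarray:
    """Sterile-specimen pattern: whole category blocks missing at once."""
    missing = np.zeros((n_specimens, len(specs)), dtype=bool)
    for category, prob in config.missing_block:
        block = np.array([s.category == category for s in specs])
        if not block.any():
            continue
        sterile = rng.random(n_specimens) < prob
        missing[np.ix_(sterile, block)] = True
    return missing


def make_queries(
    tree: ReferenceTree,
    matrix: CharacterMatrix,
    truth: SimulationTruth,
    config: SimulationConfig,
) -> tuple[CharacterMatrix, SimulationTruth]:
    """Phenotype-only queries evolved from inside known clades.

    Each query copies a uniformly chosen member of its source clade and
    takes one extra evolutionary step along a pendant branch (Mk transition
    for discrete characters, a Brownian increment re-coded with the
    reference breaks for morphometric ones). The same sterile-specimen
    missingness pattern applies.
    """
    rng = _rng(config.seed, 4)
    tp = (
        tree.mean_pendant_length()
        if config.query_pendant_length is None
        else config.query_pendant_length
    )
    if not tree.clade_map:
        raise ValueError("tree has no named clades to host queries")
    qids, qstates = [], []
    truth.query_source = {}
    for clade in sorted(tree.clade_map):
        members = sorted(tree.clade_map[clade])
        for i in range(config.n_queries_per_clade):
            source = members[int(rng.integers(len(members)))]
            src_row = matrix.row(source)
            row = []
            for j, spec in enumerate(matrix.specs):
                if spec.kind == "continuous":
                    base = truth.raw_continuous[spec.id][source]
                    val = base + rng.normal(0.0, np.sqrt(tp)) if tp > 0 else base
                    coded = code_continuous([val], spec)[0]
                    row.append(int(coded))
                else:
                    base = int(matrix.states[src_row, j])
                    if tp > 0:
                        P = MkModel(spec.n_states, truth.char_rate[spec.id]).transition(tp)
                        row.append(int(rng.choice(spec.n_states, p=P[base])))
                    else:
                        row.append(base)
            qid = f"Q_{clade}_{i + 1}"
            qids.append(qid)
            qstates.append(row)
            truth.query_source[qid] = clade
    states = np.array(qstates, dtype=int)
    missing = _inject_blockwise_missing(
        config, matrix.specs, len(qids), _rng(config.seed, 5)
    )
    queries = CharacterMatrix(
        specimen_ids=qids,
        taxon_labels=[truth.query_source[q] for q in qids],
        is_reference=np.zeros(len(qids), dtype=bool),
        states=states,
        missing_mask=missing,
        specs=list(matrix.specs),
    )
    truth.injected_missing["queries"] = missing.copy()
    return queries, truth


def combine(reference: CharacterMatrix, queries: CharacterMatrix) -> CharacterMatrix:
    """Stack reference and query specimens into one matrix."""
    return CharacterMatrix(
        specimen_ids=list(reference.specimen_ids) + list(queries.specimen_ids),
        taxon_labels=list(reference.taxon_labels) + list(queries.taxon_labels),
        is_reference=np.concatenate([reference.is_reference, queries.is_reference]),
        states=np.vstack([reference.states, queries.states]),
        missing_mask=np.vstack([reference.missing_mask, queries.missing_mask]),
        specs=list(reference.specs),
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ReferenceTree, CharacterMatrix, CharacterMatrix, SimulationTruth]:
    """Tree, reference matrix, query matrix, and truth in one call."""
    tree = simulate_tree(config)
    matrix, truth = simulate_characters(tree, config)
    queries, truth = make_queries(tree, matrix, truth, config)
    return tree, matrix, queries, truth
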