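import json

import numpy as np
import pytest

from phenobin.calibration import WeightVector, calibrate_weights, fit_character_models
from phenobin.chardata import CharacterSpec
from phenobin.errors import MissingDataError, OverlappingCladesError
from phenobin.likelihood import MkModel
from phenobin.placement import (
    EdgeScorer,
    bootstrap_placement,
    classify,
    clade_edges,
    extended_clades,
    classification_table,
    place_query,
    read_jplace,
    write_jplace,
)
from phenobin.tree import ReferenceTree

from conftest import make_matrix
from oracles import rebuild_ml_logliks, rebuild_mp_scores


def uniform_weights(matrix, criterion, value=1):
    return WeightVector(
        criterion,
        {c: value for c in matrix.character_ids},
        {c: (0, 0) for c in matrix.character_ids},
    )


@pytest.fixture
def quartet_matrix():
    return make_matrix(["A", "B", "C", "D"], [[0, 1], [0, 0], [1, 1], [1, 0]])


class TestEdgeObjectives:
    def test_mp_split_pattern_costs(self, quartet_tree):
        # binary character 0,0,1,1; query state 0 adds nothing on the
        # A, B and AB-side edges and at least one step elsewhere
        m = make_matrix(["A", "B", "C", "D"], [[0], [0], [1], [1]])
        scorer = EdgeScorer(quartet_tree, m, "MP")
        scores = scorer.query_score_matrix([0])[0]
        base = 1.0
        zero_side = {frozenset("A"), frozenset("B"), frozenset("AB")}
        for e in range(quartet_tree.n_edges):
            side = quartet_tree.edge_subtree_labels(e)
            if side in zero_side or side == frozenset("CD"):
                # the CD-side root edge is the same unrooted edge as AB
                assert scores[e] == base
            else:
                assert scores[e] >= base + 1

    @pytest.mark.parametrize("criterion", ["MP", "ML"])
    def test_equals_rebuild_and_rescore_oracle(self, criterion):
        rng = np.random.default_rng(5)
        newicks = [
            "((A:0.3,B:0.7):0.4,(C:0.2,D:0.5):0.6);",
            "(((A:0.2,B:0.4):0.3,C:0.8):0.2,(D:0.5,E:0.1):0.4);",
            "((((A:.3,B:.2):.2,C:.4):.3,(D:.5,E:.3):.2):.2,F:.6);",
        ]
        k = 3
        for nwk in newicks:
            tree = ReferenceTree.from_newick(nwk)
            labels = tree.terminal_labels
            states_row = [int(rng.integers(k)) for _ in labels]
            specs = [CharacterSpec(id="c1", kind="ordered_multistate", n_states=k)]
            m = make_matrix(labels, [[s] for s in states_row], specs=specs)
            states = dict(zip(labels, states_row))
            for q in [0, 1, 2]:
                if criterion == "MP":
                    scorer = EdgeScorer(tree, m, "MP")
                    fast = scorer.query_score_matrix([q])[0]
                    slow = rebuild_mp_scores(tree, states, True, k, q)
                    np.testing.assert_array_equal(fast, slow)
                else:
                    model = MkModel(k, 0.9, pendant_length=0.1)
                    scorer = EdgeScorer(
                        tree, m, "ML", models={"c1": model}, pendant_length=0.1
                    )
                    fast = scorer.query_score_matrix([q])[0]
                    slow = rebuild_ml_logliks(tree, states, model, q)
                    np.testing.assert_allclose(fast, slow, atol=1e-8)

    def test_root_position_invariance_of_best_placement(self):
        rotations = [
            "((A:1,B:1):1,((C:1,D:1):1,E:2):1);",
            "(((A:1,B:1):2,(C:1,D:1):1):0.5,E:1.5);",
        ]
        sides = []
        for nwk in rotations:
            tree = ReferenceTree.from_newick(nwk)
            labels = tree.terminal_labels
            by = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1}
            m = make_matrix(labels, [[by[l]] for l in labels])
            scorer = EdgeScorer(tree, m, "MP")
            res = place_query("q", [0], scorer, uniform_weights(m, "MP"))
            sides.append(tree.edge_subtree_labels(res.best_edge))
        assert sides[0] == sides[1]


class TestPlaceQuery:
    def test_self_placement_recovers_pendant_edge(self, quartet_tree, quartet_matrix):
        scorer = EdgeScorer(quartet_tree, quartet_matrix, "MP")
        w = uniform_weights(quartet_matrix, "MP")
        res = place_query("A-copy", [0, 1], scorer, w)
        assert quartet_tree.edge_subtree_labels(res.best_edge) == frozenset("A")

    def test_all_missing_query_is_error(self, quartet_tree, quartet_matrix):
        scorer = EdgeScorer(quartet_tree, quartet_matrix, "MP")
        with pytest.raises(MissingDataError):
            place_query("q", [None, None], scorer, uniform_weights(quartet_matrix, "MP"))

    def test_tie_broken_to_lowest_edge_id(self, quartet_tree):
        # one character points at A's pendant, the other at C's: the query
        # carrying both signals ties between the two pendant edges
        m = make_matrix(["A", "B", "C", "D"], [[0, 1], [1, 1], [1, 0], [1, 1]])
        scorer = EdgeScorer(quartet_tree, m, "MP")
        res = place_query("q", [0, 0], scorer, uniform_weights(m, "MP"))
        minima = np.flatnonzero(
            res.per_edge_score == res.per_edge_score.min()
        )
        assert len(minima) > 1
        assert res.best_edge == minima[0]

    def test_weight_scaling_does_not_change_best_edge(self, quartet_tree, quartet_matrix):
        scorer = EdgeScorer(quartet_tree, quartet_matrix, "MP")
        r1 = place_query("q", [1, 0], scorer, uniform_weights(quartet_matrix, "MP", 1))
        r5 = place_query("q", [1, 0], scorer, uniform_weights(quartet_matrix, "MP", 5))
        assert r1.best_edge == r5.best_edge
        np.testing.assert_allclose(5 * r1.per_edge_score, r5.per_edge_score)


class TestBootstrap:
    def test_identical_query_gets_full_support(self, quartet_tree, quartet_matrix):
        scorer = EdgeScorer(quartet_tree, quartet_matrix, "MP")
        res = bootstrap_placement(
            "A-copy", [0, 1], scorer, uniform_weights(quartet_matrix, "MP"),
            n_replicates=50, seed=3,
        )
        pend = quartet_tree.pendant_edge("A")
        assert res.bootstrap_support == {pend: 100}

    def test_single_replicate_single_edge(self, quartet_tree, quartet_matrix):
        scorer = EdgeScorer(quartet_tree, quartet_matrix, "MP")
        res = bootstrap_placement(
            "q", [1, 0], scorer, uniform_weights(quartet_matrix, "MP"),
            n_replicates=1, seed=3,
        )
        assert list(res.bootstrap_support.values()) == [100]

    @pytest.mark.parametrize("n", [16, 100, 37])
    def test_supports_sum_to_100(self, quartet_tree, quartet_matrix, n):
        scorer = EdgeScorer(quartet_tree, quartet_matrix, "MP")
        res = bootstrap_placement(
            "q", [1, 1], scorer, uniform_weights(quartet_matrix, "MP"),
            n_replicates=n, seed=9,
        )
        assert sum(res.bootstrap_support.values()) == 100

    def test_reproducible_and_order_independent(self, quartet_tree, quartet_matrix):
        scorer = EdgeScorer(quartet_tree, quartet_matrix, "MP")
        w = uniform_weights(quartet_matrix, "MP")
        a = bootstrap_placement("q", [1, 0], scorer, w, 100, seed=5)
        b = bootstrap_placement("q", [1, 0], scorer, w, 100, seed=5)
        assert a.bootstrap_support == b.bootstrap_support

    def test_weight_scaling_does_not_change_supports(self, quartet_tree, quartet_matrix):
        scorer = EdgeScorer(quartet_tree, quartet_matrix, "MP")
        a = bootstrap_placement(
            "q", [1, 0], scorer, uniform_weights(quartet_matrix, "MP", 2), 60, seed=5
        )
        b = bootstrap_placement(
            "q", [1, 0], scorer, uniform_weights(quartet_matrix, "MP", 14), 60, seed=5
        )
        assert a.bootstrap_support == b.bootstrap_support

    def test_ambiguous_query_splits_support_across_clades(self):
        tree = ReferenceTree.from_newick(
            "((A:1,B:1):1,(C:1,D:1):1);",
            clade_map={"left": frozenset("AB"), "right": frozenset("CD")},
        )
        # two characters point at A's pendant, two at C's: resamples
        # dominated by either pair land in different clades
        m = make_matrix(["A", "B", "C", "D"],
                        [[0, 0, 1, 1], [1, 1, 1, 1], [1, 1, 0, 0], [1, 1, 1, 1]])
        scorer = EdgeScorer(tree, m, "MP")
        res = bootstrap_placement(
            "q", [0, 0, 0, 0], scorer, uniform_weights(m, "MP"), 16, seed=2
        )
        per_clade = {
            name: sum(res.bootstrap_support.get(e, 0) for e in edges)
            for name, edges in clade_edges(tree).items()
        }
        assert per_clade["left"] > 0 and per_clade["right"] > 0
        assert sum(res.bootstrap_support.values()) == 100


class TestClassification:
    def make_supported(self, tree, edge_support):
        from phenobin.placement import PlacementResult

        return PlacementResult(
            query_id="q", criterion="ML",
            per_edge_score=np.zeros(tree.n_edges),
            best_edge=0, bootstrap_support=edge_support, n_replicates=100,
        )

    def test_threshold_rule(self):
        tree = ReferenceTree.from_newick(
            "((A:1,B:1):1,(C:1,D:1):1);",
            clade_map={"left": frozenset("AB"), "right": frozenset("CD")},
        )
        left_edge = tree.pendant_edge("A")
        out_edge = [
            e for e in range(tree.n_edges)
            if tree.edge_subtree_labels(e) == frozenset("CD")
        ][0]
        # 74 inside the clade -> supported (mirrors a BS=74 assignment)
        rec = classify({"ML": self.make_supported(tree, {left_edge: 74, out_edge: 26})}, tree)
        assert rec.clade_ML == "left" and rec.BS_ML == 74
        # 65 < 70 -> unsupported, but the support is still reported
        rec = classify({"ML": self.make_supported(tree, {left_edge: 65, out_edge: 35})}, tree)
        assert rec.clade_ML == "unsupported" and rec.BS_ML == 65

    def test_criteria_can_disagree(self):
        tree = ReferenceTree.from_newick(
            "((A:1,B:1):1,(C:1,D:1):1);",
            clade_map={"left": frozenset("AB"), "right": frozenset("CD")},
        )
        la = tree.pendant_edge("A")
        rc = tree.pendant_edge("C")
        ml = self.make_supported(tree, {la: 90, rc: 10})
        mp = self.make_supported(tree, {la: 10, rc: 90})
        mp.criterion = "MP"
        rec = classify({"ML": ml, "MP": mp}, tree)
        assert rec.clade_ML == "left" and rec.clade_MP == "right"
        # the secondary clade appears among alternatives at >= 5 support
        assert ("ML", "right", 10) in rec.alternatives

    def test_overlapping_clades_rejected(self):
        tree = ReferenceTree.from_newick(
            "((A:1,B:1):1,(C:1,D:1):1);",
            clade_map={"x": frozenset("AB"), "y": frozenset("BC")},
        )
        with pytest.raises(OverlappingCladesError):
            clade_edges(tree)

    def test_extended_clades_add_assigned_queries(self):
        tree = ReferenceTree.from_newick(
            "((A:1,B:1):1,(C:1,D:1):1);",
            clade_map={"left": frozenset("AB"), "right": frozenset("CD")},
        )
        la = tree.pendant_edge("A")
        rec = classify({"ML": self.make_supported(tree, {la: 100})}, tree)
        ext = extended_clades([rec], tree, "ML")
        assert ext["left"] == frozenset({"A", "B", "q"})
        assert ext["right"] == frozenset("CD")


class TestJplace:
    def test_round_trip(self, quartet_tree, quartet_matrix, tmp_path):
        scorer = EdgeScorer(quartet_tree, quartet_matrix, "MP")
        res = bootstrap_placement(
            "q1", [0, 1], scorer, uniform_weights(quartet_matrix, "MP"), 100, seed=4
        )
        path = tmp_path / "p.jplace"
        write_jplace([res], quartet_tree, path)
        doc = json.loads(path.read_text())
        assert doc["version"] == 3
        assert "edge_num" in doc["fields"] and "like_weight_ratio" in doc["fields"]
        assert all(f"{{{e}}}" in doc["tree"] for e in range(quartet_tree.n_edges))
        back = read_jplace(path)
        assert back["q1"] == res.bootstrap_support
        # best edge is recoverable as the maximal-support edge
        best = min(back["q1"], key=lambda e: (-back["q1"][e], e))
        assert back["q1"][best] == max(res.bootstrap_support.values())

    def test_empty_placement_list(self, quartet_tree, tmp_path):
        path = tmp_path / "p.jplace"
        write_jplace([], quartet_tree, path)
        doc = json.loads(path.read_text())
        assert doc["placements"] == []

    def test_classification_table_layout(self):
        from phenobin.placement import ClassificationRecord

        rec = ClassificationRecord(
            query_id="q", clade_ML="left", BS_ML=90, clade_MP="right", BS_MP=80,
            alternatives=[("ML", "right", 10)],
        )
        df = classification_table([rec])
        assert list(df.columns) == [
            "query", "clade_ML", "BS_ML", "clade_MP", "BS_MP", "alternatives"
        ]
        assert df.loc[0, "alternatives"] == "ML:right:10"
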