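import subprocess
import textwrap

import numpy as np
import pytest

from phenobin.errors import MissingDataError, ScenarioError
from phenobin.mrpp import mrpp, pairwise_distances, run_scenarios
from phenobin.scenario import (
    GroupingScenario,
    read_scenarios,
    write_scenarios,
)

from conftest import make_matrix


def scenario(groups, name="s", subset=None):
    return GroupingScenario(
        name, {g: frozenset(m) for g, m in groups.items()}, subset
    )


def one_d_matrix(values, ids=None):
    """Specimens with a single ordered character scaled by 10 (states)."""
    ids = ids or [f"s{i}" for i in range(len(values))]
    from phenobin.chardata import CharacterSpec

    specs = [
        CharacterSpec(id="c1", kind="ordered_multistate", n_states=200)
    ]
    return make_matrix(ids, [[v] for v in values], specs=specs)


class TestDistances:
    def test_identical_rows_distance_zero(self):
        m = make_matrix(["a", "b"], [[1, 0, 2], [1, 0, 2]])
        D, _ = pairwise_distances(m)
        assert D[0, 1] == 0

    def test_one_dimensional_euclidean(self):
        m = one_d_matrix([0, 3])
        D, _ = pairwise_distances(m)
        assert D[0, 1] == pytest.approx(3.0)

    def test_gower_hand_computation(self):
        # two characters with observed ranges 1 and 4; rows (0, 0) and
        # (1, 4): gower = mean(|0-1|/1, |0-4|/4) = 1
        from phenobin.chardata import CharacterSpec

        specs = [
            CharacterSpec(id="c1", kind="binary"),
            CharacterSpec(id="c2", kind="ordered_multistate", n_states=5),
        ]
        m = make_matrix(
            ["a", "b", "c"], [[0, 0], [1, 4], [0, 2]], specs=specs
        )
        D, _ = pairwise_distances(m, metric="gower")
        assert D[0, 1] == pytest.approx(1.0)
        assert D[0, 2] == pytest.approx((0.0 + 2.0 / 4.0) / 2)

    def test_pairwise_complete_rescaling(self):
        # one of two characters missing in b: the observed squared
        # difference is rescaled by 2/1 before the square root
        m = make_matrix(
            ["a", "b"],
            [[3, 1], [0, 1]],
            missing=[[False, False], [True, False]],
        )
        D, _ = pairwise_distances(m)
        # only c2 shared (diff 0) -> distance 0 after rescaling
        assert D[0, 1] == pytest.approx(0.0)

    def test_no_shared_characters_is_error(self):
        m = make_matrix(
            ["a", "b"],
            [[1, 0], [0, 1]],
            missing=[[False, True], [True, False]],
        )
        with pytest.raises(MissingDataError):
            pairwise_distances(m)


class TestScenarios:
    def test_groups_must_not_overlap(self):
        with pytest.raises(ScenarioError):
            scenario({"g1": ["a", "b"], "g2": ["b", "c"]})

    def test_groups_need_two_members(self):
        with pytest.raises(ScenarioError):
            scenario({"g1": ["a"], "g2": ["b", "c"]})

    def test_yaml_round_trip(self, tmp_path):
        sc = [
            scenario({"g1": ["a", "b"], "g2": ["c", "d"]}, name="GR01"),
            scenario(
                {"g1": ["a", "b"], "g2": ["c", "d"]},
                name="GR01_no_apothecia",
                subset=frozenset(["c1"]),
            ),
        ]
        p = tmp_path / "sc.yaml"
        write_scenarios(sc, p)
        back = read_scenarios(p)
        assert [s.name for s in back] == ["GR01", "GR01_no_apothecia"]
        assert back[0].groups == sc[0].groups
        assert back[1].character_subset == frozenset(["c1"])


class TestMRPP:
    def test_identical_within_groups_gives_A_one(self):
        m = make_matrix(
            ["a1", "a2", "a3", "b1", "b2", "b3"],
            [[0, 0]] * 3 + [[1, 2]] * 3,
        )
        D, ids = pairwise_distances(m)
        res = mrpp(D, ids, scenario({"ga": ["a1", "a2", "a3"], "gb": ["b1", "b2", "b3"]}))
        assert res.delta_obs == 0
        assert res.A == 1.0

    def test_two_cluster_exhaustive_example(self):
        # 1-D points {0, 0.1} vs {10, 10.1}: delta = 0.1,
        # expected = 6.7, A = 1 - 0.1/6.7, exact p = 1/3
        m = one_d_matrix([0, 1, 100, 101])  # states scaled x10
        D, ids = pairwise_distances(m)
        D = D / 10.0
        res = mrpp(D, ids, scenario({"g1": ["s0", "s1"], "g2": ["s2", "s3"]}))
        assert res.exhaustive
        assert res.delta_obs == pytest.approx(0.1)
        assert res.delta_expected == pytest.approx(6.7)
        assert res.A == pytest.approx(1 - 0.1 / 6.7)
        assert res.p == pytest.approx(1 / 3)

    def test_negative_A_when_groups_worse_than_chance(self):
        # pair up one member of each cluster: within-group distances are
        # the large between-cluster ones
        m = one_d_matrix([0, 1, 100, 101])
        D, ids = pairwise_distances(m)
        res = mrpp(D, ids, scenario({"g1": ["s0", "s2"], "g2": ["s1", "s3"]}))
        assert res.A < 0

    def test_scale_invariance_of_A(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 50, size=9)
        m = one_d_matrix(list(vals))
        D, ids = pairwise_distances(m)
        sc = scenario({"g1": ids[:4], "g2": ids[4:]})
        a1 = mrpp(D, ids, sc).A
        a2 = mrpp(D * 37.5, ids, sc).A
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_delta_expected_equals_enumerated_mean(self):
        rng = np.random.default_rng(3)
        m = one_d_matrix(list(rng.integers(0, 40, size=7)))
        D, ids = pairwise_distances(m)
        sc = scenario({"g1": ids[:3], "g2": ids[3:]})
        res = mrpp(D, ids, sc)
        assert res.exhaustive
        # enumerate deltas independently
        import itertools

        deltas = []
        idx = list(range(7))
        for combo in itertools.combinations(idx, 3):
            g1 = list(combo)
            g2 = [i for i in idx if i not in combo]
            x1 = np.mean([D[i, j] for i, j in itertools.combinations(g1, 2)])
            x2 = np.mean([D[i, j] for i, j in itertools.combinations(g2, 2)])
            deltas.append((3 / 7) * x1 + (4 / 7) * x2)
        assert res.delta_expected == pytest.approx(np.mean(deltas), abs=1e-12)

    def test_sampled_p_matches_exhaustive(self):
        rng = np.random.default_rng(4)
        m = one_d_matrix(list(rng.integers(0, 30, size=8)))
        D, ids = pairwise_distances(m)
        sc = scenario({"g1": ids[:4], "g2": ids[4:]})
        exact = mrpp(D, ids, sc)
        assert exact.exhaustive
        # force sampling by lowering the enumeration threshold
        import importlib

        mod = importlib.import_module("phenobin.mrpp")
        old = mod.EXHAUSTIVE_LIMIT
        mod.EXHAUSTIVE_LIMIT = 1
        try:
            sampled = mrpp(D, ids, sc, n_perm=9999, seed=1)
        finally:
            mod.EXHAUSTIVE_LIMIT = old
        assert not sampled.exhaustive
        assert abs(sampled.p - exact.p) < 0.02

    def test_degenerate_all_zero_distances_flagged(self):
        m = make_matrix(["a", "b", "c", "d"], [[1]] * 4)
        D, ids = pairwise_distances(m)
        res = mrpp(D, ids, scenario({"g1": ["a", "b"], "g2": ["c", "d"]}))
        assert res.degenerate and np.isnan(res.A)

    def test_equal_weighting_changes_delta_not_expectation(self):
        rng = np.random.default_rng(5)
        m = one_d_matrix(list(rng.integers(0, 30, size=9)))
        D, ids = pairwise_distances(m)
        sc = scenario({"g1": ids[:3], "g2": ids[3:]})
        nat = mrpp(D, ids, sc, weighting="natural")
        eq = mrpp(D, ids, sc, weighting="equal")
        assert nat.delta_expected == pytest.approx(eq.delta_expected)
        assert nat.delta_obs != eq.delta_obs

    def test_matches_vegan_oracle(self, tmp_path):
        rng = np.random.default_rng(42)
        X = rng.integers(0, 3, size=(10, 6)).astype(float)
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            X <- as.matrix(read.csv(file.path("%s", "X.csv"), header=FALSE))
            g <- c(rep(0, 5), rep(1, 5))
            r <- mrpp(dist(X), g, permutations=99, weight.type=1)
            cat(sprintf("%%.12f %%.12f %%.12f", r$delta, r$E.delta, r$A))
            """
            % tmp_path
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        v_delta, v_edelta, v_A = map(float, out.stdout.split())
        from phenobin.chardata import CharacterSpec

        specs = [
            CharacterSpec(id=f"c{j}", kind="ordered_multistate", n_states=3)
            for j in range(6)
        ]
        ids = [f"s{i}" for i in range(10)]
        m = make_matrix(ids, X.astype(int), specs=specs)
        D, dids = pairwise_distances(m)
        res = mrpp(D, dids, scenario({"a": ids[:5], "b": ids[5:]}))
        assert res.delta_obs == pytest.approx(v_delta, abs=1e-9)
        assert res.delta_expected == pytest.approx(v_edelta, abs=1e-9)
        assert res.A == pytest.approx(v_A, abs=1e-9)


class TestRunScenarios:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        m = make_matrix(
            [f"s{i}" for i in range(12)], rng.integers(0, 2, size=(12, 8))
        )
        sc = [
            scenario(
                {"g1": [f"s{i}" for i in range(6)],
                 "g2": [f"s{i}" for i in range(6, 12)]},
                name="GR01",
            )
        ]
        t1 = run_scenarios(m, sc, n_perm=199, seed=9)
        t2 = run_scenarios(m, sc, n_perm=199, seed=9)
        assert t1.equals(t2)

    def test_character_subset_row(self):
        rng = np.random.default_rng(7)
        m = make_matrix(
            [f"s{i}" for i in range(8)], rng.integers(0, 2, size=(8, 6))
        )
        groups = {
            "g1": [f"s{i}" for i in range(4)],
            "g2": [f"s{i}" for i in range(4, 8)],
        }
        sc = [
            scenario(groups, name="GR01"),
            scenario(groups, name="GR01_sub", subset=frozenset(["c1", "c2", "c3"])),
        ]
        table = run_scenarios(m, sc, n_perm=99, seed=1)
        assert len(table) == 2
        assert table.loc[0, "character_subset"] == ""
        assert set(table.loc[1, "character_subset"].split(";")) == {"c1", "c2", "c3"}
        assert table.loc[0, "A"] != table.loc[1, "A"]
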