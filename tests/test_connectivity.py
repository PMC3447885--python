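import itertools

import pytest
from hypothesis import given, settings, strategies as st

from zincluster.connectivity import (
    Assignment,
    ConnectivityDataset,
    CouplingPair,
    MetalSpin,
    MSL2_ASSIGNMENT,
    candidates_to_table,
    classify_ligands,
    enumerate_assignments,
    rank_by_violations,
    read_connectivity_csv,
)
from zincluster.errors import InfeasibleConnectivityError, MissingScoreError
from zincluster.synthetic import GeneratorConfig, make_connectivity_dataset

from _oracles import brute_force_assignments


class TestEnumerate:
    def test_msl2_dataset_nine_candidates(self, msl2_dataset):
        """With pairwise coupling constraints, metal C's completions are one
        ligand from each of A's and B's terminal sets: 3 x 3 = 9."""
        cands = enumerate_assignments(msl2_dataset)
        assert len(cands) == 9
        c_extras = {
            frozenset(a.metal_ligands("C") - {558, 561}) for a in cands
        }
        expected = {
            frozenset({x, y})
            for x in (527, 539, 544)
            for y in (546, 553, 556)
        }
        assert c_extras == expected

    def test_without_coupling_fifteen_candidates(self, msl2_dataset):
        msl2_dataset.coupling_pairs = []
        cands = enumerate_assignments(msl2_dataset)
        assert len(cands) == 15  # C(6, 2) over the six terminal ligands

    def test_fully_specified_returns_input(self, msl2_assignment):
        data = make_connectivity_dataset(truth=msl2_assignment, hidden_edges=[])
        cands = enumerate_assignments(data)
        assert len(cands) == 1
        assert cands[0].edges == msl2_assignment.edges

    def test_true_assignment_always_in_candidates(self, msl2_assignment):
        """Hiding any subset of edges never removes the truth."""
        edges = sorted(msl2_assignment.edges)
        for hidden in itertools.combinations(edges, 2):
            data = make_connectivity_dataset(
                truth=msl2_assignment, hidden_edges=list(hidden)
            )
            cands = enumerate_assignments(data)
            assert msl2_assignment.edges in {a.edges for a in cands}

    def test_matches_brute_force_oracle(self, msl2_dataset):
        cands = {a.edges for a in enumerate_assignments(msl2_dataset)}
        assert cands == brute_force_assignments(msl2_dataset)

    def test_matches_brute_force_without_couplings(self, msl2_dataset):
        msl2_dataset.coupling_pairs = []
        cands = {a.edges for a in enumerate_assignments(msl2_dataset)}
        assert cands == brute_force_assignments(msl2_dataset)

    @given(seed=st.integers(min_value=0, max_value=49))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_random_hiding_matches_oracle(self, seed):
        import random

        rng = random.Random(seed)
        hidden = rng.sample(sorted(MSL2_ASSIGNMENT.edges), 2)
        data = make_connectivity_dataset(
            truth=MSL2_ASSIGNMENT, hidden_edges=hidden, config=GeneratorConfig(seed=seed)
        )
        ours = {a.edges for a in enumerate_assignments(data)}
        assert ours == brute_force_assignments(data)
        assert MSL2_ASSIGNMENT.edges in ours

    def test_adding_confirmed_edge_is_monotone(self, msl2_dataset):
        before = {a.edges for a in enumerate_assignments(msl2_dataset)}
        msl2_dataset.confirmed_edges.add(("C", 539))
        after = {a.edges for a in enumerate_assignments(msl2_dataset)}
        assert after <= before

    def test_deterministic_order(self, msl2_dataset):
        a = enumerate_assignments(msl2_dataset)
        b = enumerate_assignments(msl2_dataset)
        assert [x.edges for x in a] == [x.edges for x in b]

    def test_oversaturated_ligand_rejected(self):
        with pytest.raises(InfeasibleConnectivityError):
            ConnectivityDataset(
                metals=[MetalSpin("A"), MetalSpin("B"), MetalSpin("C")],
                ligands=[1, 2, 3, 4, 5, 6, 7, 8, 9],
                confirmed_edges={("A", 1), ("B", 1), ("C", 1)},
            )

    def test_two_metal_shared_pair(self):
        """Two metals sharing two of six ligands: bridging size 2."""
        metals = [MetalSpin("A"), MetalSpin("B")]
        truth = Assignment(
            frozenset(
                [("A", 1), ("A", 2), ("A", 3), ("A", 4),
                 ("B", 3), ("B", 4), ("B", 5), ("B", 6)]
            )
        )
        data = ConnectivityDataset(
            metals=metals, ligands=[1, 2, 3, 4, 5, 6],
            confirmed_edges=set(truth.edges),
        )
        cands = enumerate_assignments(data)
        assert len(cands) == 1
        _, bridging = classify_ligands(cands[0])
        assert bridging == frozenset({3, 4})


class TestClassifyLigands:
    def test_msl2_assignment(self, msl2_assignment):
        terminal, bridging = classify_ligands(msl2_assignment)
        assert bridging == frozenset({525, 539, 553})
        assert terminal == frozenset({527, 544, 546, 556, 558, 561})

    def test_mononuclear_no_bridges(self):
        a = Assignment(frozenset([("A", 1), ("A", 2), ("A", 3), ("A", 4)]))
        terminal, bridging = classify_ligands(a)
        assert bridging == frozenset()
        assert terminal == frozenset({1, 2, 3, 4})


class TestRanking:
    def _candidates(self, msl2_dataset):
        return enumerate_assignments(msl2_dataset)

    def test_zero_violation_candidate_selected(self, msl2_dataset):
        cands = self._candidates(msl2_dataset)
        scores = {
            a: 0 if a.metal_ligands("C") == frozenset({539, 553, 558, 561}) else 3
            for a in cands
        }
        ranked = rank_by_violations(cands, scores)
        assert ranked[0].selected
        assert ranked[0].assignment.metal_ligands("C") == frozenset({539, 553, 558, 561})
        assert not any(r.selected for r in ranked[1:])

    def test_all_equal_keeps_order_none_selected(self, msl2_dataset):
        cands = self._candidates(msl2_dataset)
        ranked = rank_by_violations(cands, {a: 2 for a in cands})
        assert [r.assignment for r in ranked] == cands
        assert not any(r.selected for r in ranked)

    def test_two_zero_scores_ambiguous(self, msl2_dataset):
        cands = self._candidates(msl2_dataset)
        scores = {a: 1 for a in cands}
        scores[cands[0]] = 0
        scores[cands[1]] = 0
        ranked = rank_by_violations(cands, scores)
        assert not any(r.selected for r in ranked)
        assert sum(r.ambiguous for r in ranked) == 2

    def test_missing_score_raises(self, msl2_dataset):
        cands = self._candidates(msl2_dataset)
        with pytest.raises(MissingScoreError):
            rank_by_violations(cands, {a: 0 for a in cands[1:]})


def test_csv_round_trip(tmp_path, msl2_dataset):
    conn_path = tmp_path / "connectivity.csv"
    rows = ["metal,ligand_position,status"]
    for m, l in sorted(msl2_dataset.confirmed_edges):
        rows.append(f"{m},{l},confirmed")
    for l in (539, 553):
        rows.append(f",{l},candidate")
    conn_path.write_text("\n".join(rows) + "\n")
    coup_path = tmp_path / "coupling.csv"
    coup_path.write_text(
        "metal_a,metal_b,evidence\nA,B,2J\nA,C,2J\nB,C,2J\n"
    )
    data = read_connectivity_csv(conn_path, coup_path)
    assert set(data.ligands) == set(msl2_dataset.ligands)
    assert data.confirmed_edges == msl2_dataset.confirmed_edges
    assert len(enumerate_assignments(data)) == 9


def test_candidate_table_has_bridging_annotation(msl2_dataset):
    cands = enumerate_assignments(msl2_dataset)
    table = candidates_to_table(cands)
    assert len(table) == 9
    assert {"bridging", "terminal"} <= set(table.columns)
    assert all("525" in b for b in table["bridging"])
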