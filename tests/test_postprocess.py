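"""Residue graphs, sequence assignment, chain connection, pruning, scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from densid import (
    AtomicModel,
    Chain,
    Residue,
    SequenceDatabase,
    SequenceEntry,
    assign_and_mutate,
    build_residue_graph,
    connect_chains,
    gen_structure,
    prune_chains,
    rmsd_to_score,
)
from densid.postprocess import SequenceAssignment
from densid.search import SearchHit


def _line_model(xs, chain_id="A", identity="G"):
    chain = Chain(chain_id)
    for x in xs:
        chain.residues.append(Residue(identity, atoms={"CA": np.array([x, 0.0, 0.0])}))
    return AtomicModel([chain])


class TestResidueGraph:
    def test_small_system_clamps_to_n_minus_1(self):
        model = _line_model([0.0, 4.0, 8.0])
        g = build_residue_graph(model, k=20)
        assert all(len(nb) == 2 for nb in g.neighbors)

    def test_helix_degree_is_k(self):
        model = gen_structure([100], seed=2)
        g = build_residue_graph(model, k=20)
        assert all(len(nb) == 20 for nb in g.neighbors)

    def test_no_self_edges_or_duplicates(self):
        model = gen_structure([50], seed=3)
        g = build_residue_graph(model, k=10)
        for i, nb in enumerate(g.neighbors):
            assert i not in nb
            assert len(set(nb.tolist())) == len(nb)

    def test_matches_brute_force_on_random_points(self, rng):
        n, k = 50, 12
        chain = Chain("A")
        pts = rng.uniform(0, 30, size=(n, 3))
        for p in pts:
            chain.residues.append(Residue("G", atoms={"CA": p}))
        g = build_residue_graph(AtomicModel([chain]), k=k)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        for i in range(n):
            order = sorted((d[i, j], j) for j in range(n) if j != i)
            expected = [j for _, j in order[:k]]
            assert g.neighbors[i].tolist() == expected

    def test_brute_force_up_to_200(self, rng):
        for n in (5, 37, 200):
            chain = Chain("A")
            pts = rng.uniform(0, 50, size=(n, 3))
            for p in pts:
                chain.residues.append(Residue("G", atoms={"CA": p}))
            g = build_residue_graph(AtomicModel([chain]), k=20)
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            kk = min(20, n - 1)
            for i in range(n):
                order = sorted((d[i, j], j) for j in range(n) if j != i)
                assert g.neighbors[i].tolist() == [j for _, j in order[:kk]]

    def test_too_few_residues(self):
        with pytest.raises(ValueError):
            build_residue_graph(_line_model([0.0]))


def _db(seqs: dict[str, str]) -> SequenceDatabase:
    return SequenceDatabase([SequenceEntry(k, v) for k, v in seqs.items()])


def _all_match_hit(chain_id, target, n, target_offset=0):
    ali = [(i + 1, i + 1 + target_offset, "M") for i in range(n)]
    return SearchHit(target_id=target, bit_score=50.0, e_value=1e-9,
                     alignment=ali, query_chain=chain_id)


class TestAssignAndMutate:
    def test_all_match_substitution(self):
        model = _line_model([0, 4, 8], identity="G")
        db = _db({"T": "MKV"})
        out, asg = assign_and_mutate(model, {"A": _all_match_hit("A", "T", 3)}, db)
        assert [r.identity for r in out.residues()] == ["M", "K", "V"]
        assert [r.seq_pos for r in out.residues()] == [1, 2, 3]
        assert asg.targets["A"] == "T"

    def test_delete_state_keeps_identity(self):
        model = _line_model([0, 4, 8], identity="W")
        db = _db({"T": "MKV"})
        ali = [(1, 1, "M"), (2, 1, "D"), (3, 2, "M")]
        hit = SearchHit("T", 10.0, 1e-3, ali, "A")
        out, _ = assign_and_mutate(model, {"A": hit}, db)
        ids = [r.identity for r in out.residues()]
        assert ids[0] == "M"
        assert ids[1] == "W"  # unmatched: keeps its identity
        assert ids[2] == "K"
        assert out.chains[0].residues[1].seq_pos is None

    def test_unmatched_as_unk_flag(self):
        model = _line_model([0, 4, 8], identity="W")
        db = _db({"T": "MKV"})
        ali = [(1, 1, "M"), (3, 2, "M")]
        hit = SearchHit("T", 10.0, 1e-3, ali, "A")
        out, _ = assign_and_mutate(model, {"A": hit}, db, unmatched_as_unk=True)
        assert [r.identity for r in out.residues()] == ["M", "X", "K"]

    def test_chain_without_hit_unchanged(self):
        model = _line_model([0, 4, 8], identity="W")
        out, asg = assign_and_mutate(model, {}, _db({"T": "MKV"}))
        assert [r.identity for r in out.residues()] == ["W", "W", "W"]
        assert asg.targets == {}

    def test_alignment_beyond_chain_length_errors(self):
        model = _line_model([0, 4], identity="G")
        db = _db({"T": "MKV"})
        with pytest.raises(ValueError, match="beyond"):
            assign_and_mutate(model, {"A": _all_match_hit("A", "T", 3)}, db)

    def test_residue_count_conserved(self):
        model = gen_structure([10, 20], seed=5)
        db = _db({"T": "M" * 10})
        out, _ = assign_and_mutate(model, {"A": _all_match_hit("A", "T", 10)}, db)
        assert out.n_residues == model.n_residues


def _two_fragment_setup(gap_distance):
    """Two 10-residue chains matched to positions 1-10 and 11-20 of T."""
    xs_a = [3.8 * i for i in range(10)]
    start_b = xs_a[-1] + gap_distance
    xs_b = [start_b + 3.8 * i for i in range(10)]
    model = AtomicModel(
        [_line_model(xs_a, "A").chains[0], _line_model(xs_b, "B").chains[0]]
    )
    asg = SequenceAssignment(
        targets={"A": "T", "B": "T"},
        positions={"A": np.arange(1, 11), "B": np.arange(11, 21)},
    )
    return model, asg


class TestConnectChains:
    def test_adjacent_fragments_merge(self):
        model, asg = _two_fragment_setup(3.8)
        out = connect_chains(model, asg)
        assert len(out.chains) == 1
        assert len(out.chains[0]) == 20

    def test_distant_fragments_do_not_merge(self):
        model, asg = _two_fragment_setup(50.0)
        out = connect_chains(model, asg)
        assert len(out.chains) == 2

    def test_different_targets_never_merge(self):
        model, asg = _two_fragment_setup(3.8)
        asg.targets["B"] = "OTHER"
        out = connect_chains(model, asg)
        assert len(out.chains) == 2

    def test_gap_scales_distance_allowance(self):
        # gap of 4 residues: up to 5 * 3.8 = 19 A is allowed
        model, asg = _two_fragment_setup(15.0)
        asg.positions["B"] = np.arange(15, 25)
        out = connect_chains(model, asg)
        assert len(out.chains) == 1
        model2, asg2 = _two_fragment_setup(25.0)
        asg2.positions["B"] = np.arange(15, 25)
        assert len(connect_chains(model2, asg2).chains) == 2

    def test_residue_count_conserved(self):
        model, asg = _two_fragment_setup(3.8)
        assert connect_chains(model, asg).n_residues == model.n_residues


class TestPruneChains:
    def test_four_residue_threshold(self):
        chains = []
        for n in range(1, 11):
            ch = _line_model([4.0 * i for i in range(n)], chain_id=f"C{n}").chains[0]
            chains.append(ch)
        out = prune_chains(AtomicModel(chains))
        lengths = sorted(len(c) for c in out.chains)
        assert lengths == list(range(4, 11))

    def test_min_len_one_is_identity(self):
        model = gen_structure([1, 2, 3], seed=1)
        assert prune_chains(model, min_len=1).n_residues == model.n_residues

    def test_connected_fragments_survive_pruning(self):
        # two 2-residue fragments merge to 4 residues, then survive pruning
        xs_a = [0.0, 3.8]
        xs_b = [7.6, 11.4]
        model = AtomicModel(
            [_line_model(xs_a, "A").chains[0], _line_model(xs_b, "B").chains[0]]
        )
        asg = SequenceAssignment(
            targets={"A": "T", "B": "T"},
            positions={"A": np.array([1, 2]), "B": np.array([3, 4])},
        )
        merged = connect_chains(model, asg)
        out = prune_chains(merged)
        assert out.n_residues == 4
        # pruning before connection would have dropped both fragments
        assert prune_chains(model).n_residues == 0


class TestRmsdToScore:
    def test_endpoints(self):
        assert rmsd_to_score(0.5) == pytest.approx(1.0)
        assert rmsd_to_score(1.2) == pytest.approx(0.0)

    def test_midpoint(self):
        assert rmsd_to_score(0.85) == pytest.approx(0.5)

    def test_saturation(self):
        assert rmsd_to_score(0.0) == 1.0
        assert rmsd_to_score(10.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rmsd_to_score(-0.1)

    @given(st.floats(0, 5), st.floats(0, 5))
    @settings(max_examples=200, deadline=None)
    def test_non_increasing(self, a, b):
        lo, hi = sorted((a, b))
        assert rmsd_to_score(lo) >= rmsd_to_score(hi)
        assert 0.0 <= rmsd_to_score(a) <= 1.0
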