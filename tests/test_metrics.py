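"""Residue matching, RMSD, classification metrics, Q-score and FSC."""

import numpy as np
import pytest

from densid import (
    AtomicModel,
    Chain,
    DensityMap,
    Residue,
    classification_metrics,
    evaluate_model,
    fsc,
    gen_structure,
    match_residues,
    perturb_model,
    qscore,
    render_map,
    rmsd_metrics,
)


def _translate(model, vec):
    out = model.copy()
    for res in out.residues():
        for name in res.atoms:
            res.atoms[name] = res.atoms[name] + np.asarray(vec, dtype=float)
    return out


class TestMatchResidues:
    def test_identical_models_all_paired_at_zero(self, helix_model):
        corr = match_residues(helix_model, helix_model)
        assert len(corr.pairs) == helix_model.n_residues
        assert all(d == 0.0 for _, _, d in corr.pairs)

    def test_rigid_shift_beyond_cutoff_gives_no_pairs(self):
        # straight chain shifted perpendicular to its axis: every
        # cross-distance is exactly 5 A, beyond the 3 A cutoff
        chain = Chain("A", [Residue("G", atoms={"CA": np.array([4.0 * i, 0.0, 0.0])})
                            for i in range(20)])
        ref = AtomicModel([chain])
        shifted = _translate(ref, [0.0, 5.0, 0.0])
        corr = match_residues(shifted, ref, cutoff=3.0)
        assert corr.pairs == []
        assert len(corr.unmatched_ref) == 20

    def test_symmetry_of_pair_count(self, helix_model, rng):
        pred = perturb_model(helix_model, sigma_xyz=0.5, seed=3)
        c1 = match_residues(pred, helix_model)
        c2 = match_residues(helix_model, pred)
        assert len(c1.pairs) == len(c2.pairs)

    def test_matches_brute_force_mutual_nn(self, rng):
        n = 30
        ref_pts = rng.uniform(0, 40, size=(n, 3))
        pred_pts = ref_pts + rng.normal(0, 0.4, size=(n, 3))
        ref = AtomicModel([Chain("R", [Residue("G", atoms={"CA": p}) for p in ref_pts])])
        pred = AtomicModel([Chain("P", [Residue("G", atoms={"CA": p}) for p in pred_pts])])
        corr = match_residues(pred, ref, cutoff=3.0)
        d = np.linalg.norm(pred_pts[:, None] - ref_pts[None, :], axis=2)
        expected = {
            (ip, int(d[ip].argmin()))
            for ip in range(n)
            if d[:, d[ip].argmin()].argmin() == ip and d[ip].min() <= 3.0
        }
        got = {(p[1], r[1]) for p, r, _ in corr.pairs}
        assert got == expected


class TestRmsd:
    def test_identity_is_zero(self, helix_model):
        corr = match_residues(helix_model, helix_model)
        assert rmsd_metrics(corr, helix_model, helix_model) == 0.0

    def test_uniform_translation_exact(self, helix_model):
        pred = _translate(helix_model, [1.0 / np.sqrt(3)] * 3)
        corr = match_residues(pred, helix_model)
        rmsd = rmsd_metrics(corr, pred, helix_model, atoms=("CA", "C", "N", "O"))
        assert rmsd == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_jitter_recovers_sigma_sqrt3(self):
        model = gen_structure([125], seed=9)  # 500 backbone atoms
        sigma = 0.3
        pred = perturb_model(model, sigma_xyz=sigma, seed=10)
        corr = match_residues(pred, model)
        rmsd = rmsd_metrics(corr, pred, model, atoms=("CA", "C", "N", "O"))
        expected = sigma * np.sqrt(3)
        # pooled over 500 atoms: relative sampling error ~ 1/sqrt(2*1500)
        assert rmsd == pytest.approx(expected, rel=0.1)

    def test_no_eligible_atoms(self, helix_model):
        corr = match_residues(helix_model, helix_model)
        with pytest.raises(ValueError):
            rmsd_metrics(corr, helix_model, helix_model, atoms=("P",))


class TestClassification:
    def test_identical_models_all_ones(self, helix_model):
        corr = match_residues(helix_model, helix_model)
        cls = classification_metrics(corr, helix_model, helix_model)
        assert cls["recall"] == cls["precision"] == 1.0
        assert cls["aa_accuracy"] == cls["completeness"] == 1.0

    def test_one_wrong_identity_of_ten(self):
        ref = gen_structure([10], seed=4)
        pred = ref.copy()
        res = pred.chains[0].residues[3]
        res.identity = "W" if res.identity != "W" else "Y"
        corr = match_residues(pred, ref)
        cls = classification_metrics(corr, pred, ref)
        assert cls["recall"] == 1.0
        assert cls["aa_accuracy"] == pytest.approx(0.9)
        assert cls["completeness"] == pytest.approx(0.9)

    def test_two_missing_of_ten(self):
        ref = gen_structure([10], seed=4)
        pred = ref.copy()
        pred.chains[0].residues = pred.chains[0].residues[:8]
        corr = match_residues(pred, ref)
        cls = classification_metrics(corr, pred, ref)
        assert cls["recall"] == pytest.approx(0.8)
        assert cls["precision"] == 1.0
        assert cls["completeness"] == pytest.approx(0.8)

    def test_identity_error_rate_recovered(self):
        model = gen_structure([1000], seed=6)
        rate = 0.1
        pred = perturb_model(model, identity_error_rate=rate, seed=7)
        corr = match_residues(pred, model)
        cls = classification_metrics(corr, pred, model)
        se = np.sqrt(rate * (1 - rate) / 1000)
        assert abs((1 - cls["aa_accuracy"]) - rate) < 4 * se

    def test_ratio_invariants_on_random_instances(self, rng):
        for seed in range(5):
            model = gen_structure([40], seed=seed)
            pred = perturb_model(
                model,
                sigma_xyz=float(rng.uniform(0, 2.0)),
                identity_error_rate=float(rng.uniform(0, 0.5)),
                seed=seed + 100,
            )
            corr = match_residues(pred, model)
            cls = classification_metrics(corr, pred, model)
            for key in ("recall", "precision", "aa_accuracy", "completeness"):
                assert 0.0 <= cls[key] <= 1.0
            assert cls["completeness"] <= cls["recall"]


class TestQScore:
    def test_isolated_atom_self_consistency(self):
        model = AtomicModel(
            [Chain("A", [Residue("G", atoms={"CA": np.array([6.0, 6.0, 6.0])})])]
        )
        dmap = render_map(model, voxel=0.4, sigma=0.6, box_pad=4.0)
        res = qscore(model, dmap, sigma=0.6)
        assert res.model_q > 0.99

    def test_separated_atoms_self_consistency(self):
        chain = Chain("A")
        for i in range(10):
            chain.residues.append(
                Residue("G", atoms={"CA": np.array([8.0 * i, 0.0, 0.0])})
            )
        model = AtomicModel([chain])
        dmap = render_map(model, voxel=0.4, sigma=0.6, box_pad=4.0)
        res = qscore(model, dmap, sigma=0.6)
        assert res.model_q > 0.99
        assert res.n_skipped == 0

    def test_noise_map_mean_q_near_zero(self, rng):
        chain = Chain("A")
        pts = rng.uniform(8, 24, size=(100, 3))
        for p in pts:
            chain.residues.append(Residue("G", atoms={"CA": p}))
        model = AtomicModel([chain])
        grid = rng.normal(size=(64, 64, 64)).astype(np.float32)
        dmap = DensityMap(grid, np.full(3, 0.5), np.zeros(3))
        res = qscore(model, dmap, sigma=0.6)
        assert abs(res.model_q) < 0.15

    def test_affine_invariance(self):
        model = gen_structure([10], seed=3)
        dmap = render_map(model, voxel=0.5, sigma=0.6, box_pad=4.0)
        scaled = DensityMap(3.5 * dmap.grid + 1.2, dmap.voxel_size, dmap.origin)
        q1 = qscore(model, dmap, sigma=0.6)
        q2 = qscore(model, scaled, sigma=0.6)
        assert q1.model_q == pytest.approx(q2.model_q, abs=1e-5)

    def test_atom_near_edge_skipped(self):
        model = AtomicModel(
            [Chain("A", [Residue("G", atoms={"CA": np.array([0.5, 5.0, 5.0])})])]
        )
        grid = np.ones((20, 20, 20), dtype=np.float32)
        dmap = DensityMap(grid, np.full(3, 0.5), np.zeros(3))
        with pytest.warns(UserWarning):
            res = qscore(model, dmap, sigma=0.6)
        assert res.n_skipped == 1


class TestFsc:
    def test_self_correlation_is_one(self):
        model = gen_structure([8], seed=2)
        dmap = render_map(model, voxel=1.0, sigma=0.8)
        _, corr, _ = fsc(dmap, dmap)
        assert np.allclose(corr, 1.0)

    def test_negated_map_is_minus_one(self):
        model = gen_structure([8], seed=2)
        dmap = render_map(model, voxel=1.0, sigma=0.8)
        neg = DensityMap(-dmap.grid, dmap.voxel_size, dmap.origin)
        _, corr, _ = fsc(dmap, neg)
        assert np.allclose(corr, -1.0)

    def test_noise_decorrelates_high_frequencies(self, rng):
        model = gen_structure([20], seed=2)
        dmap = render_map(model, voxel=1.0, sigma=1.0)
        noisy = DensityMap(
            dmap.grid + rng.normal(0, 0.5, dmap.grid.shape).astype(np.float32),
            dmap.voxel_size,
            dmap.origin,
        )
        freqs, corr, crossing = fsc(dmap, noisy)
        # correlation trend decreases with frequency
        third = len(corr) // 3
        assert corr[:third].mean() > corr[-third:].mean()
        assert crossing is None or freqs[0] < crossing < freqs[-1]

    def test_mismatched_grids_error(self):
        a = DensityMap(np.zeros((8, 8, 8)), np.ones(3), np.zeros(3))
        b = DensityMap(np.zeros((8, 8, 10)), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError):
            fsc(a, b)


def test_evaluate_model_report(helix_model):
    pred = perturb_model(helix_model, sigma_xyz=0.2, identity_error_rate=0.1, seed=8)
    report = evaluate_model(pred, helix_model)
    d = report.to_dict()
    assert 0.0 <= d["completeness"] <= d["recall"] <= 1.0
    assert d["calpha_rmsd"] > 0
    assert len(report.per_residue) == d["n_pairs"]
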