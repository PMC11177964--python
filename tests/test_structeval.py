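import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from topoddg.structeval import (
    ComplexEvaluation,
    bfactor_rmsd_table,
    kabsch_superpose,
    map_chains,
    per_residue_rmsd,
    summarize_and_rank,
    superpose_complexes,
)
from topoddg.structure_io import Atom, Structure
from topoddg.synthetic import (
    ToyDimerConfig,
    make_toy_dimer,
    perturb_structure,
    random_rigid_motion,
)


def renamed(structure, mapping):
    atoms = [
        Atom(a.element, a.coords.copy(), mapping.get(a.chain, a.chain),
             a.res_seq, a.res_name, a.name, a.b_factor)
        for a in structure.atoms
    ]
    return Structure(structure.id, atoms, {})


class TestMapChains:
    def test_identity_with_renamed_chains(self, toy_dimer):
        pred = renamed(toy_dimer, {"A": "X", "B": "Y"})
        assert map_chains(pred, toy_dimer) == {"X": "A", "Y": "B"}

    def test_homodimer_swap_resolved_by_rmsd(self):
        """Two identical-sequence chains: the assignment with the lower
        whole-complex RMSD after superposition must win."""
        base = make_toy_dimer(ToyDimerConfig(residues_per_chain=12, interface_contacts=0, seed=1))
        # make both chains the same sequence: copy chain A, shift it
        atoms_a = [a for a in base.atoms if a.chain == "A"]
        atoms_b = [
            Atom(a.element, a.coords + np.array([15.0, 0, 0]), "B", a.res_seq,
                 a.res_name, a.name, a.b_factor)
            for a in atoms_a
        ]
        ref = Structure("HOMO", atoms_a + atoms_b, {"A": "P1", "B": "P2"})
        pred = renamed(ref, {"A": "B", "B": "A"})  # swapped chain order
        mapping = map_chains(pred, ref)
        res = superpose_complexes(pred, ref, chain_map=mapping)
        assert res.rmsd < 1e-6
        assert mapping == {"B": "A", "A": "B"}

    def test_missing_chain_errors(self, toy_dimer):
        only_a = Structure(
            "PART", [a for a in toy_dimer.atoms if a.chain == "A"], {}
        )
        with pytest.raises(ValueError, match="chains"):
            map_chains(only_a, toy_dimer)


class TestKabsch:
    def test_identical_coordinates(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        res = kabsch_superpose(x, x)
        assert res.rmsd < 1e-12
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_copy_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(25, 3))
        rot, trans = random_rigid_motion(rng)
        res = kabsch_superpose(x @ rot.T + trans, x)
        assert res.rmsd <= 1e-9
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_numerical_minimization(self):
        """Unit square with one vertex displaced 1 Å out of plane: compare
        against a direct numerical minimum over rotations + translations."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        fixed = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float
        )
        moving = fixed.copy()
        moving[2, 2] = 1.0

        def objective(params):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            return np.sqrt(
                np.mean(np.sum((moving @ rot.T + params[3:] - fixed) ** 2, axis=1))
            )

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000}).fun
            for x0 in [np.zeros(6), np.array([0.3, -0.2, 0.1, 0, 0, 0])]
        )
        res = kabsch_superpose(moving, fixed)
        assert res.rmsd == pytest.approx(best, abs=1e-6)

    def test_matches_reference_superimposer(self):
        """Independent oracle: Biopython's SVD superimposer."""
        from Bio.SVDSuperimposer import SVDSuperimposer

        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 3))
        y = x + rng.normal(scale=0.5, size=(12, 3))
        sup = SVDSuperimposer()
        sup.set(x, y)
        sup.run()
        assert kabsch_superpose(y, x).rmsd == pytest.approx(sup.get_rms(), abs=1e-9)

    def test_symmetry_of_direction(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(15, 3))
        b = a + rng.normal(scale=0.8, size=(15, 3))
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_global_rmsd_is_quadratic_mean(self, toy_dimer):
        pred = perturb_structure(
            toy_dimer, {k: 0.5 for k in toy_dimer.residues()}, seed=4
        )
        res = superpose_complexes(pred, toy_dimer, chain_map={"A": "A", "B": "B"})
        moved = res.transform(np.array([a.coords for a in pred.atoms if a.name == "CA"]))
        ref = np.array([a.coords for a in toy_dimer.atoms if a.name == "CA"])
        direct = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
        assert res.rmsd == pytest.approx(direct, abs=1e-9)


class TestPerResidue:
    def test_identical_structures_all_zero(self, toy_dimer):
        aln = superpose_complexes(toy_dimer, toy_dimer, chain_map={"A": "A", "B": "B"})
        table = per_residue_rmsd(toy_dimer, toy_dimer, aln.chain_map, aln)
        assert (table["rmsd"] < 1e-9).all()
        assert len(table) == len(toy_dimer.residues())

    def test_single_displaced_residue_stands_out(self):
        ref = make_toy_dimer(ToyDimerConfig(residues_per_chain=40, interface_contacts=0, seed=2))
        profile = {k: 0.0 for k in ref.residues()}
        profile[("A", "7")] = 2.0
        pred = perturb_structure(ref, profile, seed=8)
        aln = superpose_complexes(pred, ref, chain_map={"A": "A", "B": "B"})
        table = per_residue_rmsd(pred, ref, aln.chain_map, aln)
        top = table.loc[table["rmsd"].idxmax()]
        assert (top["chain"], top["res_seq"]) == ("A", "7")
        assert top["rmsd"] == pytest.approx(2.0, abs=0.1)
        others = table[~((table["chain"] == "A") & (table["res_seq"] == "7"))]
        assert others["rmsd"].max() < 0.2

    def test_missing_backbone_atom_uses_common_subset(self, toy_dimer):
        pruned_atoms = [
            a for a in toy_dimer.atoms if not (a.name == "O" and a.res_seq == "3" and a.chain == "A")
        ]
        pred = Structure("PRUNED", pruned_atoms, {})
        aln = superpose_complexes(pred, toy_dimer, chain_map={"A": "A", "B": "B"})
        table = per_residue_rmsd(pred, toy_dimer, aln.chain_map, aln)
        row = table[(table["chain"] == "A") & (table["res_seq"] == "3")].iloc[0]
        assert row["n_atoms"] == 3 and row["rmsd"] < 1e-9


class TestBfactorTable:
    def test_displacement_proportional_to_bfactor(self):
        ref = make_toy_dimer(ToyDimerConfig(residues_per_chain=50, interface_contacts=0, seed=5))
        profile = {
            k: 0.05 * np.mean([a.b_factor for a in atoms])
            for k, atoms in ref.residues().items()
        }
        pred = perturb_structure(ref, profile, seed=6,
                                 rigid_motion=random_rigid_motion(np.random.default_rng(7)))
        aln = superpose_complexes(pred, ref, chain_map={"A": "A", "B": "B"})
        table = bfactor_rmsd_table(ref, per_residue_rmsd(pred, ref, aln.chain_map, aln))
        rho = spearmanr(table["b_factor"], table["rmsd"]).statistic
        assert rho >= 0.9

    def test_identical_structures_zero_rmsd_any_b(self, toy_dimer):
        aln = superpose_complexes(toy_dimer, toy_dimer, chain_map={"A": "A", "B": "B"})
        table = bfactor_rmsd_table(
            toy_dimer, per_residue_rmsd(toy_dimer, toy_dimer, aln.chain_map, aln)
        )
        assert (table["rmsd"] < 1e-9).all()
        assert table["aa"].nunique() <= 20

    def test_all_zero_bfactors_flagged(self):
        ref = make_toy_dimer(ToyDimerConfig(residues_per_chain=5, interface_contacts=0, seed=1))
        zeroed = Structure(
            "ZB",
            [Atom(a.element, a.coords, a.chain, a.res_seq, a.res_name, a.name, 0.0)
             for a in ref.atoms],
            dict(ref.partition),
        )
        aln = superpose_complexes(zeroed, zeroed, chain_map={"A": "A", "B": "B"})
        table = bfactor_rmsd_table(
            zeroed, per_residue_rmsd(zeroed, zeroed, aln.chain_map, aln)
        )
        assert table.attrs["zero_bfactors"]


def make_evals(triples):
    return [
        ComplexEvaluation(cid, rmsd, iptm, ptm)
        for cid, rmsd, iptm, ptm in triples
    ]


class TestSummarizeAndRank:
    def test_threshold_fractions(self):
        evals = make_evals(
            [("A1", 1.0, 0.9, 0.9), ("B2", 2.0, 0.7, 0.6), ("C3", 3.0, 0.85, 0.4)]
        )
        s = summarize_and_rank(evals)
        assert s["frac_iptm_high"] == pytest.approx(2 / 3)
        assert s["frac_iptm_low"] == 0.0
        assert s["frac_ptm_good"] == pytest.approx(2 / 3)

    def test_intersection_of_poor_lists(self):
        # six complexes engineered poor in both RMSD and ipTM
        poor = [(f"P{i}", 10.0 + i, 0.3, 0.6) for i in range(6)]
        good_rmsd = [(f"G{i}", 0.5, 0.2 + 0.01 * i, 0.7) for i in range(37)]
        good_iptm = [(f"H{i}", 5.0 + 0.01 * i, 0.95, 0.9) for i in range(37)]
        s = summarize_and_rank(make_evals(poor + good_rmsd + good_iptm), top_n=40)
        assert sorted(s["poor_in_both"]) == sorted(p[0] for p in poor)

    def test_single_complex_means(self):
        s = summarize_and_rank(make_evals([("X", 1.5, 0.8, 0.9)]))
        assert (s["mean_rmsd"], s["mean_iptm"], s["mean_ptm"]) == (1.5, 0.8, 0.9)

    def test_order_invariance_with_stable_ties(self):
        evals = make_evals(
            [("B", 2.0, 0.5, 0.9), ("A", 2.0, 0.5, 0.9), ("C", 1.0, 0.9, 0.9)]
        )
        s1 = summarize_and_rank(evals, top_n=2)
        s2 = summarize_and_rank(list(reversed(evals)), top_n=2)
        assert s1["top_by_rmsd"] == s2["top_by_rmsd"] == ["A", "B"]
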