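import numpy as np
import pytest

from topoddg.features import (
    FeatureConfig,
    LaplacianFeaturizer,
    assemble_features,
    build_mutant,
    filtration_features,
    spectral_statistics,
)
from topoddg.laplacian import LaplacianSpectrum
from topoddg.structure_io import Atom, Structure, parse_mutation_code
from topoddg.synthetic import ToyDimerConfig, make_toy_dimer, random_rigid_motion

from conftest import make_structure

SMALL_CONFIG = FeatureConfig(
    element_pairs=(("C", "C"), ("N", "O")),
    grid_dim0=(0.0, 2.0, 4.0, 6.0, 8.0),
    grid_dim12=(0.0, 2.0, 4.0),
)


def spec_of(values):
    v = np.sort(np.asarray(values, dtype=float))
    return LaplacianSpectrum(0, 0.0, 0.0, v, zero_tol=1e-8)


class TestSpectralStatistics:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0, 0, 3, 3], [2, 3, 3, 3, 0, 6, 0, 1]),
            ([0], [1, 0, 0, 0, 0, 0, 0, 0]),
            ([0, 2, 4], [1, 2, 4, 3, 1, 6, 1, 1]),
        ],
    )
    def test_examples(self, values, expected):
        np.testing.assert_allclose(spectral_statistics(spec_of(values)), expected)


@pytest.fixture
def mutation_and_dimer(toy_dimer):
    res = toy_dimer.residue_atoms("B", "2")[0].res_name
    from topoddg.structure_io import AA3_TO_1

    wt = AA3_TO_1[res]
    mut = parse_mutation_code(f"{wt}B2{'G' if wt != 'G' else 'A'}")
    return toy_dimer, mut


class TestFiltrationFeatures:
    def test_component_merge_lowers_harmonic_count(self):
        """Two cross-partner carbons merge into one component once the grid
        value passes their distance; β0 drops by one, matching the rank
        oracle at both grid values."""
        st = make_structure(
            [("A", 1, "ALA", (0, 0, 0)), ("B", 1, "ALA", (4, 0, 0))],
            partition={"A": "P1", "B": "P2"},
        )
        mut = parse_mutation_code("AA1G")
        cfg = FeatureConfig(
            element_pairs=(("C", "C"),),
            site_types=("interface",),
            grid_dim0=(1.0, 8.0),
            dims=(0,),
            persistence_steps=0,
        )
        block = filtration_features(st, mut, cfg)
        betti_low, betti_high = block[0], block[8]
        assert betti_high < betti_low

        from topoddg.filtration import build_rips, snapshot
        from topoddg.laplacian import betti_by_rank
        from topoddg.sites import filter_by_element, pairwise_distances, select_binding_site

        atoms = filter_by_element(
            select_binding_site(st, "P1", cfg.r_binding), ["C"]
        ) + filter_by_element(select_binding_site(st, "P2", cfg.r_binding), ["C"])
        dm = pairwise_distances(atoms, atoms, mode="mod", grouping=lambda a: a.chain)
        cx = build_rips(dm, 1, 10.0)
        assert betti_low == betti_by_rank(snapshot(cx, 1.0), 0)
        assert betti_high == betti_by_rank(snapshot(cx, 8.0), 0)

    def test_same_partner_subset_stays_disconnected(self):
        """With every atom in one group, the modified distance keeps all
        vertices isolated: harmonic multiplicity equals the vertex count."""
        st = make_structure(
            [("A", 1, "ALA", (0, 0, 0)), ("A", 2, "ALA", (3, 0, 0)),
             ("B", 1, "ALA", (30, 0, 0))],
            partition={"A": "P1", "B": "P2"},
        )
        mut = parse_mutation_code("AA1G")
        # mutation-site carbons vs themselves: ALA has 3 C in site, but the
        # neighborhood group is empty at tiny r, so every vertex is isolated
        cfg = FeatureConfig(
            element_pairs=(("C", "C"),),
            site_types=("mutation",),
            r_neighborhood=0.01,
            grid_dim0=(5.0,),
            dims=(0,),
            persistence_steps=0,
        )
        block = filtration_features(st, mut, cfg)
        assert block[0] == 3.0  # betti = number of carbon vertices
        assert block[7] == 0.0  # no non-harmonic spectrum at all

    def test_denser_grid_extends_schema_consistently(self, mutation_and_dimer):
        st, mut = mutation_and_dimer
        cfg1 = FeatureConfig(
            element_pairs=(("C", "C"),), site_types=("interface",),
            grid_dim0=(0.0, 4.0, 8.0), dims=(0,), persistence_steps=0,
        )
        cfg2 = FeatureConfig(
            element_pairs=(("C", "C"),), site_types=("interface",),
            grid_dim0=(0.0, 2.0, 4.0, 6.0, 8.0, 10.0), dims=(0,), persistence_steps=0,
        )
        b1 = filtration_features(st, mut, cfg1)
        b2 = filtration_features(st, mut, cfg2)
        assert b2.size == 2 * b1.size
        s1, s2 = cfg1.schema(), cfg2.schema()
        shared = {n: b2[i] for i, n in enumerate(s2) if n in set(s1)}
        for i, n in enumerate(s1):
            np.testing.assert_allclose(b1[i], shared[n], atol=1e-12)


class TestAssembleFeatures:
    def test_identity_mutation_zero_difference(self, mutation_and_dimer):
        st, mut = mutation_and_dimer
        with pytest.warns(UserWarning):
            fv = assemble_features(st, st, mut, SMALL_CONFIG)
        third = fv.values.size // 3
        assert np.abs(fv.values[2 * third:]).max() == 0.0

    def test_displaced_interface_atom_changes_dim0(self, mutation_and_dimer):
        st, mut = mutation_and_dimer
        mutant = build_mutant(st, mut)
        fv = assemble_features(st, mutant, mut, SMALL_CONFIG)
        third = fv.values.size // 3
        diff = fv.values[2 * third:]
        k0 = [i for i, n in enumerate(fv.schema[2 * third:]) if "|k0|" in n]
        assert np.abs(diff[k0]).max() > 0

    def test_deterministic_across_runs(self, mutation_and_dimer):
        st, mut = mutation_and_dimer
        mutant = build_mutant(st, mut)
        a = assemble_features(st, mutant, mut, SMALL_CONFIG)
        b = assemble_features(st, mutant, mut, SMALL_CONFIG)
        assert a.values.tobytes() == b.values.tobytes()
        assert a.schema == b.schema and a.config_hash == b.config_hash

    @pytest.fixture
    def generic_pair(self):
        """Dimer with coordinate noise: no cospherical point sets, so the
        Delaunay triangulation (hence the Alpha complex) is unique and the
        geometric invariances hold exactly; the idealized noise-free helix
        has symmetric ties that floating-point Delaunay may break either way."""
        st = make_toy_dimer(
            ToyDimerConfig(residues_per_chain=20, interface_contacts=5,
                           noise_sigma=0.05, seed=9)
        )
        res = st.residue_atoms("B", "2")[0].res_name
        from topoddg.structure_io import AA3_TO_1

        mut = parse_mutation_code(f"{AA3_TO_1[res]}B2G")
        return st, mut

    def test_rigid_motion_invariance(self, generic_pair):
        st, mut = generic_pair
        mutant = build_mutant(st, mut)
        base = assemble_features(st, mutant, mut, SMALL_CONFIG).values
        rot, trans = random_rigid_motion(np.random.default_rng(5))

        def moved(s):
            atoms = [
                Atom(a.element, rot @ a.coords + trans, a.chain, a.res_seq,
                     a.res_name, a.name, a.b_factor)
                for a in s.atoms
            ]
            return Structure(s.id, atoms, dict(s.partition))

        got = assemble_features(moved(st), moved(mutant), mut, SMALL_CONFIG).values
        np.testing.assert_allclose(got, base, atol=1e-6)

    def test_atom_order_invariance(self, generic_pair):
        st, mut = generic_pair
        mutant = build_mutant(st, mut)
        base = assemble_features(st, mutant, mut, SMALL_CONFIG).values
        rng = np.random.default_rng(3)

        def shuffled(s):
            idx = rng.permutation(len(s.atoms))
            return Structure(s.id, [s.atoms[i] for i in idx], dict(s.partition))

        got = assemble_features(shuffled(st), shuffled(mutant), mut, SMALL_CONFIG).values
        np.testing.assert_allclose(got, base, atol=1e-9)

    def test_plugin_slot_appends(self, mutation_and_dimer):
        st, mut = mutation_and_dimer
        mutant = build_mutant(st, mut)
        fv = assemble_features(st, mutant, mut, SMALL_CONFIG, extra=np.ones(4))
        assert fv.schema[-1] == "extra|3" and fv.values[-4:].tolist() == [1] * 4


class TestBuildMutant:
    def test_truncates_to_backbone_cb(self, toy_dimer):
        from topoddg.structure_io import AA3_TO_1

        res = toy_dimer.residue_atoms("A", "1")[0].res_name
        mut = parse_mutation_code(f"{AA3_TO_1[res]}A1W")
        mutant = build_mutant(toy_dimer, mut)
        names = {a.name for a in mutant.residue_atoms("A", "1")}
        assert names == {"N", "CA", "C", "O", "CB"}
        assert mutant.residue_atoms("A", "1")[0].res_name == "TRP"

    def test_to_glycine_drops_cb(self, toy_dimer):
        from topoddg.structure_io import AA3_TO_1

        res = toy_dimer.residue_atoms("A", "1")[0].res_name
        mut = parse_mutation_code(f"{AA3_TO_1[res]}A1G")
        mutant = build_mutant(toy_dimer, mut)
        assert "CB" not in {a.name for a in mutant.residue_atoms("A", "1")}


class TestLaplacianFeaturizer:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        fz = LaplacianFeaturizer(dims=(0,), grid_dim0=(0.0, 4.0))
        params = fz.get_params()
        assert params["dims"] == (0,)
        clone(fz)  # must not raise

    def test_transform_shape_and_names(self, mutation_and_dimer):
        st, mut = mutation_and_dimer
        fz = LaplacianFeaturizer(
            element_pairs=(("C", "C"),),
            site_types=("interface",),
            grid_dim0=(0.0, 4.0, 8.0),
            dims=(0,),
            persistence_steps=0,
        ).fit()
        X = fz.transform([(st, None, mut), (st, build_mutant(st, mut), mut)])
        assert X.shape == (2, fz.n_features_out_)
        names = fz.get_feature_names_out()
        assert len(names) == X.shape[1]
        assert names[0].startswith("wt|interface|CC|k0|")
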