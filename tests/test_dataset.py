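"""Dipeptide extraction, geometry generation and dataset assembly."""

import numpy as np
import pytest

from pattnet.crystal import (
    Atom,
    AtomList,
    UnitCell,
    patterson_from_reflections,
    reflections_from_density,
    structure_factors,
)
from pattnet.dataset import (
    Dataset,
    DatasetConfig,
    build_dataset,
    center_by_mass,
    clash_check,
    extract_dipeptide,
    make_example,
    truncate_to_dialanine,
)
from pattnet.io import read_pdb
from pattnet.peptides import (
    AMINO_ACIDS,
    HEAVY_ATOM_COUNTS,
    chiral_volume,
    synth_dipeptide,
)


class TestSynthDipeptide:
    def test_deterministic_per_seed(self):
        a = synth_dipeptide(("LEU", "TRP"), 7)
        b = synth_dipeptide(("LEU", "TRP"), 7)
        np.testing.assert_array_equal(a.coords(), b.coords())
        c = synth_dipeptide(("LEU", "TRP"), 8)
        assert not np.array_equal(a.coords(), c.coords())

    def test_dialanine_has_ten_heavy_atoms(self):
        assert len(synth_dipeptide(("ALA", "ALA"), 0)) == 10

    @pytest.mark.parametrize("pair,count", [
        (("GLY", "GLY"), 8),
        (("LYS", "SER"), 15),
        (("TRP", "ARG"), 25),
    ])
    def test_heavy_atom_counts_match_residue_topology(self, pair, count):
        assert len(synth_dipeptide(pair, 3)) == count
        assert count == HEAVY_ATOM_COUNTS[pair[0]] + HEAVY_ATOM_COUNTS[pair[1]]

    def test_alpha_carbons_always_l_configured(self):
        """The fixed protein chirality that breaks the Patterson inversion
        ambiguity: the N,C,CB triple product at every CA must stay positive."""
        rng = np.random.default_rng(0)
        for draw in range(1000):
            pair = tuple(rng.choice(AMINO_ACIDS, size=2))
            mol = synth_dipeptide(pair, draw)
            pos = {(a.res_index, a.name): a.xyz for a in mol}
            for ri, resname in zip((1, 2), pair):
                if resname == "GLY":
                    continue
                vol = chiral_volume(pos[(ri, "N")], pos[(ri, "CA")],
                                    pos[(ri, "C")], pos[(ri, "CB")])
                assert vol > 0.5

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            synth_dipeptide(("ALA", "XYZ"), 0)

    def test_bonded_geometry_plausible(self):
        mol = synth_dipeptide(("ALA", "ALA"), 11)
        pos = {(a.res_index, a.name): a.xyz for a in mol}
        peptide_bond = np.linalg.norm(pos[(1, "C")] - pos[(2, "N")])
        assert peptide_bond == pytest.approx(1.329, abs=1e-6)


class TestExtractDipeptide:
    def test_returns_all_heavy_atoms_of_adjacent_pair(self, demo_pdb):
        structure = read_pdb(demo_pdb)
        pair = extract_dipeptide(structure, 1)
        assert pair.label == "GLY-ALA"
        assert len(pair) == 9  # 4 Gly + 5 Ala heavy atoms
        assert {a.res_index for a in pair} == {1, 2}

    def test_first_altloc_kept_once(self, demo_pdb):
        pair = extract_dipeptide(read_pdb(demo_pdb), 1)
        cb = [a for a in pair if a.name == "CB"]
        assert len(cb) == 1

    def test_numbering_gap_is_extraction_error(self, demo_pdb):
        with pytest.raises(ValueError, match="chain break|adjacent"):
            extract_dipeptide(read_pdb(demo_pdb), 3)  # residue 4 missing

    def test_hetatm_never_extracted(self, demo_pdb):
        structure = read_pdb(demo_pdb)
        assert all(r["resname"] != "HOH" for r in structure)


class TestTruncateToDialanine:
    def test_dialanine_unchanged(self):
        mol = synth_dipeptide(("ALA", "ALA"), 5)
        out = truncate_to_dialanine(mol)
        assert len(out) == len(mol)
        np.testing.assert_array_equal(out.coords(), mol.coords())
        assert all(a.resname == "ALA" for a in out)

    def test_lysine_serine_truncates_to_ten_atoms(self):
        out = truncate_to_dialanine(synth_dipeptide(("LYS", "SER"), 5))
        assert len(out) == 10
        assert {a.name for a in out} == {"N", "CA", "C", "O", "CB"}

    def test_glycine_keeps_four_atoms_and_gains_no_cb(self):
        out = truncate_to_dialanine(synth_dipeptide(("GLY", "PHE"), 5))
        gly_atoms = [a for a in out if a.res_index == 1]
        assert len(gly_atoms) == 4
        assert "CB" not in {a.name for a in gly_atoms}
        assert all(a.resname == "ALA" for a in out)

    def test_missing_backbone_atom_rejected(self):
        mol = synth_dipeptide(("ALA", "ALA"), 5)
        broken = AtomList([a for a in mol if not (a.res_index == 2
                                                  and a.name == "CA")])
        with pytest.raises(ValueError, match="backbone"):
            truncate_to_dialanine(broken)


class TestCenterByMass:
    def test_single_atom_lands_at_cell_center(self):
        cell = UnitCell.cubic(10.0)
        out = center_by_mass(AtomList([Atom("C", [1.0, 2.0, 3.0])]), cell)
        np.testing.assert_allclose(out.coords()[0], [5.0, 5.0, 5.0])

    def test_equal_masses_place_symmetrically(self):
        cell = UnitCell.cubic(10.0)
        atoms = AtomList([Atom("C", [0.0, 0.0, 0.0]), Atom("C", [2.0, 0.0, 0.0])])
        out = center_by_mass(atoms, cell)
        np.testing.assert_allclose(out.coords(),
                                   [[4.0, 5.0, 5.0], [6.0, 5.0, 5.0]])

    def test_recomputed_centroid_is_cell_center(self, rng):
        cell = UnitCell(8.0, 9.0, 11.0)
        for _ in range(5):
            mol = synth_dipeptide(tuple(rng.choice(AMINO_ACIDS, 2)),
                                  int(rng.integers(1000)))
            out = center_by_mass(mol, cell)
            masses = out.masses()
            centroid = masses @ out.coords() / masses.sum()
            np.testing.assert_allclose(centroid, cell.edges / 2, atol=1e-10)


class TestClashCheck:
    def test_single_atom_passes(self):
        assert clash_check(AtomList([Atom("C", [1, 1, 1])]), UnitCell.cubic(10.0))

    def test_periodic_image_contact_fails(self):
        cell = UnitCell.cubic(10.0)
        atoms = AtomList([Atom("C", [0.5, 5.0, 5.0]), Atom("C", [9.5, 5.0, 5.0])])
        assert not clash_check(atoms, cell, min_dist=2.0)  # image distance 1 A

    def test_same_pair_passes_with_smaller_threshold(self):
        cell = UnitCell.cubic(10.0)
        atoms = AtomList([Atom("C", [0.5, 5.0, 5.0]), Atom("C", [9.5, 5.0, 5.0])])
        assert clash_check(atoms, cell, min_dist=0.5)

    def test_bonded_pair_is_not_a_clash(self):
        cell = UnitCell.cubic(10.0)
        atoms = AtomList([Atom("C", [5.0, 5.0, 5.0]), Atom("N", [6.4, 5.0, 5.0])])
        assert clash_check(atoms, cell, min_dist=2.0)

    def test_nonbonded_close_pair_fails(self):
        cell = UnitCell.cubic(10.0)
        atoms = AtomList([Atom("C", [4.0, 5.0, 5.0]), Atom("O", [5.95, 5.0, 5.0])])
        assert not clash_check(atoms, cell, min_dist=2.0)


class TestMakeExample:
    CFG = DatasetConfig(cell_edge=10.0, spacing=0.5, seed=0)

    def test_single_atom_blob_at_center_and_origin_patterson_peak(self):
        pair = make_example(AtomList([Atom("C", [0, 0, 0])]), self.CFG)
        d, P = pair.density.values, pair.patterson.values
        assert np.unravel_index(np.argmax(d), d.shape) == (10, 10, 10)
        assert np.unravel_index(np.argmax(P), P.shape) == (0, 0, 0)

    def test_maps_normalized_into_unit_range(self):
        pair = make_example(synth_dipeptide(("ALA", "ALA"), 1), self.CFG)
        for v in (pair.density.values, pair.patterson.values):
            assert v.min() >= -1.0 and v.max() <= 1.0
            assert v.min() == -1.0 and v.max() == 1.0  # min-max endpoints

    def test_inverted_twin_same_patterson_different_density(self):
        mol = synth_dipeptide(("ALA", "ALA"), 2)
        twin = mol.inverted(mol.coords().mean(axis=0))
        a = make_example(mol, self.CFG)
        b = make_example(twin, self.CFG)
        np.testing.assert_allclose(a.patterson.values, b.patterson.values,
                                   atol=1e-8)
        assert np.max(np.abs(a.density.values - b.density.values)) > 0.1


class TestBuildDataset:
    def test_reproducible_and_correctly_split(self):
        cfg = DatasetConfig(cell_edge=10.0, spacing=0.5, seed=9,
                            train_fraction=0.9)
        ds1 = build_dataset(cfg, 10)
        ds2 = build_dataset(cfg, 10)
        assert len(ds1) == 10
        np.testing.assert_array_equal(ds1.pattersons, ds2.pattersons)
        assert ds1.manifest.to_json() == ds2.manifest.to_json()
        assert len(ds1.manifest.split_indices("train")) == 9
        assert len(ds1.manifest.split_indices("validation")) == 1

    def test_no_source_leaks_across_splits(self):
        cfg = DatasetConfig(cell_edge=10.0, spacing=0.5, seed=3)
        ds = build_dataset(cfg, 8)
        train = {ds.manifest.records[i]["source"]
                 for i in ds.manifest.split_indices("train")}
        val = {ds.manifest.records[i]["source"]
               for i in ds.manifest.split_indices("validation")}
        assert train and val and not (train & val)

    def test_grid_shape_follows_cell_and_spacing(self):
        cfg = DatasetConfig(cell_edge=10.0, spacing=0.5, seed=0)
        ds = build_dataset(cfg, 2)
        assert ds.pattersons.shape[1:] == (20, 20, 20)

    def test_stored_patterson_consistent_with_density_amplitudes(self):
        """The stored Patterson must be re-derivable from its own density's
        reflection amplitudes (pre-normalization internal consistency)."""
        cfg = DatasetConfig(cell_edge=10.0, spacing=0.5, seed=4)
        mol = truncate_to_dialanine(synth_dipeptide(("ALA", "ALA"), 12))
        centered = center_by_mass(mol, cfg.cell)
        rset = structure_factors(centered, cfg.cell, cfg.d_min)
        from pattnet.crystal import density_from_reflections

        rho = density_from_reflections(rset, cfg.grid)
        back = reflections_from_density(rho, cfg.d_min)
        P_direct = patterson_from_reflections(rset, cfg.grid).values
        P_rederived = patterson_from_reflections(back, cfg.grid).values
        assert np.max(np.abs(P_direct - P_rederived)) <= 1e-6 * np.max(np.abs(P_direct))

    def test_enlarged_cell_has_empty_border_density(self):
        """Dialanine in a 20 A cell: density outside the central 12 A cube is
        background-level, the empty margin that disambiguates vector origins."""
        cfg = DatasetConfig(cell_edge=20.0, spacing=0.5, seed=5)
        mol = truncate_to_dialanine(synth_dipeptide(("ALA", "ALA"), 3))
        centered = center_by_mass(mol, cfg.cell)
        rset = structure_factors(centered, cfg.cell, cfg.d_min)
        from pattnet.crystal import density_from_reflections

        rho = density_from_reflections(rset, cfg.grid).values
        n = rho.shape[0]
        lo, hi = int(0.2 * n), int(0.8 * n)
        border = rho.copy()
        border[lo:hi, lo:hi, lo:hi] = 0.0
        assert np.max(np.abs(border)) <= 0.1 * np.max(rho)

    def test_hdf5_round_trip(self, tmp_path):
        cfg = DatasetConfig(cell_edge=10.0, spacing=0.5, seed=1)
        ds = build_dataset(cfg, 3)
        path = tmp_path / "ds.h5"
        ds.save(path)
        back = Dataset.load(path)
        np.testing.assert_allclose(back.densities, ds.densities, atol=1e-6)
        assert back.manifest.config == ds.manifest.config
        assert back.manifest.records == ds.manifest.records
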