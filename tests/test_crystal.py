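"""Crystallographic core: enumeration, structure factors, syntheses, invariants."""

import numpy as np
import pytest

from pattnet import oracles
from pattnet.crystal import (
    Atom,
    AtomList,
    MapGrid,
    ReflectionSet,
    UnitCell,
    density_from_reflections,
    enumerate_hkl,
    normalize_map,
    patterson_from_reflections,
    reflections_from_density,
    structure_factors,
)
from pattnet.crystal import VoxelMap

from conftest import random_atoms


class TestEnumerateHkl:
    def test_no_reflection_reaches_very_low_resolution(self):
        assert len(enumerate_hkl(UnitCell.cubic(10.0), 20.0)) == 0

    def test_friedel_unique_count_cubic(self):
        # full sphere h^2+k^2+l^2 <= 4 holds {6,12,8,6} vectors for norms
        # {1,2,3,4}; halving Friedel pairs leaves 16
        rset = enumerate_hkl(UnitCell.cubic(10.0), 5.0)
        assert len(rset) == 16

    def test_inclusive_boundary_and_exclusions(self):
        rset = enumerate_hkl(UnitCell.cubic(10.0), 5.0)
        keys = {tuple(h) for h in rset.hkl}
        assert (2, 0, 0) in keys  # d = 5.0 exactly: retained
        assert (2, 1, 0) not in keys and (-2, -1, 0) not in keys  # d = 4.47
        assert (0, 0, 0) not in keys

    def test_no_friedel_pair_stored_twice(self):
        rset = enumerate_hkl(UnitCell(6.0, 8.0, 10.0), 2.0)
        keys = {tuple(h) for h in rset.hkl}
        assert all(tuple(-h) not in keys for h in rset.hkl)
        assert all(d >= 2.0 - 1e-9 for d in rset.d_spacings())

    def test_nonpositive_dmin_rejected(self):
        with pytest.raises(ValueError):
            enumerate_hkl(UnitCell.cubic(10.0), 0.0)


class TestStructureFactors:
    def test_atom_at_origin_gives_flat_amplitude_zero_phase(self):
        atoms = AtomList([Atom("C", [0, 0, 0], f=6, b_iso=0.0)])
        rset = structure_factors(atoms, UnitCell.cubic(10.0), 5.0)
        assert np.allclose(rset.amplitude, 6.0)
        assert np.allclose(rset.phase_deg, 0.0)

    def test_quarter_cell_offset_gives_90_degrees(self):
        atoms = AtomList([Atom("C", [2.5, 0, 0], f=1, b_iso=0.0)])
        rset = structure_factors(atoms, UnitCell.cubic(10.0), 5.0)
        i = [j for j, h in enumerate(rset.hkl) if tuple(h) == (1, 0, 0)][0]
        assert rset.amplitude[i] == pytest.approx(1.0)
        assert rset.phase_deg[i] == pytest.approx(90.0)

    def test_two_atom_systematic_absence(self):
        atoms = AtomList(
            [Atom("C", [0, 0, 0], f=1, b_iso=0.0),
             Atom("C", [5.0, 0, 0], f=1, b_iso=0.0)]
        )
        rset = structure_factors(atoms, UnitCell.cubic(10.0), 3.0)
        by_key = {tuple(h): a for h, a in zip(rset.hkl, rset.amplitude)}
        assert by_key[(1, 0, 0)] == pytest.approx(0.0, abs=1e-12)
        assert by_key[(3, 0, 0)] == pytest.approx(0.0, abs=1e-12)
        assert by_key[(2, 0, 0)] == pytest.approx(2.0)

    def test_agrees_with_direct_summation_oracle(self, rng, small_cell):
        atoms = random_atoms(rng, small_cell, 5)
        rset = structure_factors(atoms, small_cell, 1.5)
        for i in rng.choice(len(rset), size=40, replace=False):
            ref = oracles.direct_structure_factor(atoms, small_cell,
                                                  tuple(rset.hkl[i]))
            assert abs(ref - rset.complex_values[i]) <= 1e-10 * abs(ref)

    def test_f000_is_sum_of_scattering_weights(self, rng, small_cell):
        atoms = random_atoms(rng, small_cell, 4)
        rset = structure_factors(atoms, small_cell, 2.0)
        assert rset.f000 == pytest.approx(np.sum(atoms.weights()))

    def test_empty_atom_list_rejected(self, small_cell):
        with pytest.raises(ValueError):
            structure_factors(AtomList([]), small_cell, 2.0)


class TestDensitySynthesis:
    def test_f000_only_gives_constant_map(self, small_cell, small_grid):
        rset = ReflectionSet(small_cell, 2.0, np.empty((0, 3), dtype=int),
                             f000=small_cell.volume)
        rho = density_from_reflections(rset, small_grid, include_f000=True)
        assert np.allclose(rho.values, 1.0)

    def test_single_friedel_pair_gives_cosine_wave(self, small_cell, small_grid):
        rset = ReflectionSet(small_cell, 2.0, np.array([[1, 0, 0]]),
                             np.array([small_cell.volume / 2]), np.array([0.0]))
        rho = density_from_reflections(rset, small_grid).values
        x = np.arange(16) / 16
        assert np.allclose(rho, np.cos(2 * np.pi * x)[:, None, None], atol=1e-12)

    def test_matches_per_voxel_direct_summation(self, rng, small_cell, small_grid):
        atoms = random_atoms(rng, small_cell, 3)
        rset = structure_factors(atoms, small_cell, 1.25)
        rho = density_from_reflections(rset, small_grid).values
        ref = oracles.direct_density(rset, small_grid)
        assert np.max(np.abs(rho - ref)) <= 1e-8 * np.max(np.abs(ref))

    def test_aliasing_grid_rejected(self, small_cell):
        coarse = MapGrid(small_cell, 4, 4, 4)  # spacing 2.0 > d_min/2
        rset = structure_factors(
            AtomList([Atom("C", [1, 1, 1])]), small_cell, 1.5
        )
        with pytest.raises(ValueError, match="alias"):
            density_from_reflections(rset, coarse)


class TestPattersonSynthesis:
    def test_origin_is_global_maximum_and_map_centrosymmetric(
            self, rng, small_cell, small_grid):
        atoms = random_atoms(rng, small_cell, 1)
        P = patterson_from_reflections(
            structure_factors(atoms, small_cell, 1.25), small_grid
        ).values
        assert np.unravel_index(np.argmax(P), P.shape) == (0, 0, 0)
        flipped = P[np.ix_(*(np.mod(-np.arange(n), n) for n in P.shape))]
        np.testing.assert_allclose(P, flipped, atol=1e-10 * np.max(np.abs(P)))

    def test_two_equal_atoms_produce_cross_vector_peaks(self):
        # separation 0.2 fractional (2 A) along x: peaks at u = 0, 0.2, 0.8;
        # light B sharpens the atoms so the cross vector resolves from origin
        cell = UnitCell.cubic(10.0)
        atoms = AtomList(
            [Atom("C", [2.0, 5.0, 5.0], b_iso=5.0),
             Atom("C", [4.0, 5.0, 5.0], b_iso=5.0)]
        )
        grid = MapGrid(cell, 20, 20, 20)
        P = patterson_from_reflections(
            structure_factors(atoms, cell, 1.25), grid
        ).values
        line = P[:, 0, 0]
        assert line[4] == pytest.approx(line[16], rel=1e-9)  # equal cross peaks
        assert line[0] > 1.8 * line[4]  # origin ~2x higher (band-limited)
        # they are local maxima along the line
        for i in (0, 4, 16):
            assert line[i] >= line[(i - 1) % 20] and line[i] >= line[(i + 1) % 20]

    def test_equals_scaled_autocorrelation_of_density(self, rng, small_cell,
                                                      small_grid):
        atoms = random_atoms(rng, small_cell, 4)
        rset = structure_factors(atoms, small_cell, 1.25)
        P = patterson_from_reflections(rset, small_grid).values
        rho = density_from_reflections(rset, small_grid).values
        auto = oracles.circular_autocorrelation(rho)
        scaled = auto * small_cell.volume / rho.size
        assert np.max(np.abs(P - scaled)) <= 1e-6 * np.max(np.abs(P))


class TestReflectionsFromDensity:
    def test_constant_map_transforms_to_pure_f000(self, small_cell, small_grid):
        vmap = VoxelMap(small_grid, np.ones(small_grid.shape))
        rset = reflections_from_density(vmap, 2.0)
        assert rset.f000 == pytest.approx(small_cell.volume)
        assert np.all(rset.amplitude <= 1e-8)

    def test_round_trip_recovers_amplitudes_and_phases(self, rng, small_cell,
                                                       small_grid):
        atoms = random_atoms(rng, small_cell, 4)
        rset = structure_factors(atoms, small_cell, 1.25)
        rho = density_from_reflections(rset, small_grid)
        back = reflections_from_density(rho, 1.25)
        np.testing.assert_array_equal(back.hkl, rset.hkl)
        scale = np.max(rset.amplitude)
        np.testing.assert_allclose(back.amplitude, rset.amplitude,
                                   atol=1e-8 * scale)
        # compare as complex to avoid phase ambiguity of near-zero amplitudes
        np.testing.assert_allclose(back.complex_values, rset.complex_values,
                                   atol=1e-8 * scale)

    def test_cosine_wave_transforms_to_single_pair(self, small_cell, small_grid):
        x = np.arange(16) / 16
        vmap = VoxelMap(small_grid, np.broadcast_to(
            np.cos(2 * np.pi * x)[:, None, None], small_grid.shape).copy())
        rset = reflections_from_density(vmap, 2.0)
        by_key = {tuple(h): (a, p) for h, a, p in
                  zip(rset.hkl, rset.amplitude, rset.phase_deg)}
        amp, phase = by_key[(1, 0, 0)]
        assert amp == pytest.approx(small_cell.volume / 2)
        assert phase == pytest.approx(0.0, abs=1e-9)
        others = [a for k, (a, _) in by_key.items() if k != (1, 0, 0)]
        assert np.all(np.array(others) <= 1e-8 * amp)


class TestNormalizeMap:
    def test_affine_endpoints(self, small_grid):
        values = np.zeros(small_grid.shape)
        values.flat[:3] = [0.0, 2.0, 4.0]
        values.flat[3:] = 2.0
        out = normalize_map(VoxelMap(small_grid, values)).values
        assert out.flat[0] == -1.0 and out.flat[1] == 0.0 and out.flat[2] == 1.0

    def test_idempotent(self, rng, small_grid):
        vmap = VoxelMap(small_grid, rng.normal(size=small_grid.shape))
        once = normalize_map(vmap)
        twice = normalize_map(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-14)

    def test_constant_map_becomes_zero(self, small_grid):
        out = normalize_map(VoxelMap(small_grid, np.full(small_grid.shape, 7.0)))
        assert np.all(out.values == 0.0)

    def test_nonfinite_rejected(self, small_grid):
        values = np.zeros(small_grid.shape)
        values[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            normalize_map(VoxelMap(small_grid, values))

    def test_maxabs_mode_preserves_zero(self, small_grid):
        values = np.zeros(small_grid.shape)
        values[0, 0, 0] = 4.0
        values[1, 0, 0] = -2.0
        out = normalize_map(VoxelMap(small_grid, values), mode="maxabs").values
        assert out[0, 0, 0] == 1.0 and out[1, 0, 0] == -0.5
        assert out[2, 0, 0] == 0.0


class TestPattersonInvariants:
    @pytest.mark.parametrize("trial", range(3))
    def test_translation_invariance(self, trial, small_cell, small_grid):
        rng = np.random.default_rng(100 + trial)
        atoms = random_atoms(rng, small_cell, int(rng.integers(2, 6)))
        P0 = patterson_from_reflections(
            structure_factors(atoms, small_cell, 1.25), small_grid).values
        shifted = atoms.translated(rng.random(3) * small_cell.edges)
        P1 = patterson_from_reflections(
            structure_factors(shifted, small_cell, 1.25), small_grid).values
        assert np.max(np.abs(P0 - P1)) <= 1e-8 * np.max(np.abs(P0))

    @pytest.mark.parametrize("trial", range(3))
    def test_centrosymmetric_twin_shares_patterson(self, trial, small_cell,
                                                   small_grid):
        rng = np.random.default_rng(200 + trial)
        atoms = random_atoms(rng, small_cell, int(rng.integers(2, 6)))
        P0 = patterson_from_reflections(
            structure_factors(atoms, small_cell, 1.25), small_grid).values
        twin = atoms.inverted(rng.random(3) * small_cell.edges)
        P1 = patterson_from_reflections(
            structure_factors(twin, small_cell, 1.25), small_grid).values
        assert np.max(np.abs(P0 - P1)) <= 1e-8 * np.max(np.abs(P0))


class TestReflectionTsv:
    def test_round_trip(self, rng, small_cell):
        atoms = random_atoms(rng, small_cell, 3)
        rset = structure_factors(atoms, small_cell, 2.0)
        back = ReflectionSet.from_tsv(rset.to_tsv())
        np.testing.assert_array_equal(back.hkl, rset.hkl)
        np.testing.assert_allclose(back.amplitude, rset.amplitude, rtol=1e-9)
        np.testing.assert_allclose(back.phase_deg, rset.phase_deg, atol=1e-8)
        assert back.cell.a == rset.cell.a and back.d_min == rset.d_min
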