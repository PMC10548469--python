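import math

import numpy as np
import pytest

from synthgrid.crystal_structures import (
    AtomSite,
    CrystalStructure,
    MillerIndex,
    StructureError,
    SymOp,
    UnitCell,
    d_spacing,
)
from synthgrid.fixtures import make_rocksalt, make_sc_lj, toy_params
from synthgrid.forcefield import Body, KCAL_COULOMB_CONSTANT
from synthgrid.slab_builder import (
    Slab,
    Termination,
    attachment_energy,
    bfdh_faces,
    build_slab,
    lattice_energy,
    rugosity,
    scan_terminations,
    surface_aligned_cell,
)

TRICLINIC_CELL = UnitCell(9.968, 11.207, 13.394, 100.86, 104.42, 101.63)


def sc_lj(a=1.0):
    s = make_sc_lj(a, d0=1.0, r0=a)
    return s, toy_params(s.toy_types, cutoff=1.3 * a)


class TestSurfaceAlignment:
    def test_cubic_001_is_unchanged(self):
        s, _ = sc_lj(4.0)
        al = surface_aligned_cell(s, (0, 0, 1))
        assert np.allclose(al.matrix, np.diag([4.0, 4.0, 4.0]))
        assert al.layer_spacing == pytest.approx(4.0)

    def test_cubic_110_interlayer_spacing(self):
        s, _ = sc_lj(4.0)
        al = surface_aligned_cell(s, (1, 1, 0))
        assert al.layer_spacing == pytest.approx(4 / math.sqrt(2), rel=1e-12)
        assert abs(al.matrix[0, 2]) < 1e-12 and abs(al.matrix[1, 2]) < 1e-12

    @pytest.mark.parametrize("hkl", [(1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 2),
                                     (2, 1, 0), (1, 2, 3), (0, 2, 1), (3, -2, 1)])
    def test_in_plane_vectors_perpendicular_to_normal(self, hkl):
        sites = [AtomSite("C", "C1", np.array([0.1, 0.2, 0.3]), 0.0, "C_3")]
        s = CrystalStructure(TRICLINIC_CELL, sites)
        al = surface_aligned_cell(s, hkl)
        normal = np.array([0.0, 0.0, 1.0])
        assert abs(al.matrix[0] @ normal) < 1e-9
        assert abs(al.matrix[1] @ normal) < 1e-9
        # third vector advances exactly one d-spacing along the normal
        assert al.matrix[2, 2] == pytest.approx(d_spacing(TRICLINIC_CELL, hkl), rel=1e-9)

    @pytest.mark.parametrize("hkl", [(1, 1, 0), (1, 2, 3), (3, -2, 1)])
    def test_volume_and_atom_content_preserved(self, hkl):
        sites = [AtomSite("C", "C1", np.array([0.1, 0.2, 0.3]), 0.0, "C_3"),
                 AtomSite("N", "N1", np.array([0.6, 0.7, 0.8]), 0.0, "N_3")]
        s = CrystalStructure(TRICLINIC_CELL, sites)
        al = surface_aligned_cell(s, hkl)
        assert np.linalg.det(al.matrix) == pytest.approx(
            np.linalg.det(s.matrix), rel=1e-9)
        assert len(al.sites) == s.expand_p1().natoms


class TestLatticeEnergy:
    def test_simple_cubic_lj_nearest_neighbor_sum(self):
        s, params = sc_lj(1.0)
        result = lattice_energy(s, params, radius=1.3)
        assert result.total == pytest.approx(-3.0, abs=1e-12)

    def test_gas_phase_limit_below_nearest_neighbor_cutoff(self):
        s, _ = sc_lj(1.0)
        params = toy_params(s.toy_types, cutoff=0.9)
        result = lattice_energy(s, params, radius=3.0)
        assert result.total == 0.0

    def test_rocksalt_recovers_madelung_constant(self):
        a_nn = 3.2
        s = make_rocksalt(a_nn, 1.0)
        params = toy_params(cutoff=np.inf)
        result = lattice_energy(s, params, radius=None, cell_shells=4)
        # 4 formula units per cell; E = -M k q^2 / a_nn per formula unit
        madelung = -result.energy.electrostatic / 4 * a_nn / KCAL_COULOMB_CONSTANT
        assert madelung == pytest.approx(1.7476, rel=0.01)
        assert result.neutral

    def test_requires_exactly_one_truncation_mode(self):
        s, params = sc_lj(1.0)
        with pytest.raises(ValueError):
            lattice_energy(s, params, radius=5.0, cell_shells=3)


class TestAttachmentEnergy:
    def test_simple_cubic_slice_and_attachment_hand_count(self):
        s, params = sc_lj(1.0)
        t = attachment_energy(s, (0, 0, 1), 0.0, params, radius=2.5)
        assert t.e_slice == pytest.approx(-2.0, abs=1e-12)
        assert t.e_att == pytest.approx(-1.0, abs=1e-12)
        assert t.e_latt == pytest.approx(-3.0, abs=1e-12)

    def test_single_atom_basis_offsets_all_equivalent(self):
        s, params = sc_lj(1.0)
        scan = scan_terminations(s, (0, 0, 1), params, radius=2.5)
        atts = {round(t.e_att, 12) for t in scan.terminations}
        assert len(atts) == 1
        assert scan.selected.offset == 0.0

    @pytest.mark.parametrize("hkl", [(0, 0, 1), (0, 1, 0), (0, 1, 1)])
    @pytest.mark.parametrize("offset", [0.0, 0.3, 0.7])
    def test_partition_identity_on_molecular_crystal(self, bilayer_crystal, hkl,
                                                     offset, params):
        t = attachment_energy(bilayer_crystal, hkl, offset, params, radius=14.0)
        assert t.partition_error < 1e-6 * max(abs(t.e_latt), 1.0)

    def test_attachment_magnitude_bounded_by_lattice_energy(self, bilayer_crystal,
                                                            params):
        for offset in (0.0, 0.25, 0.5):
            t = attachment_energy(bilayer_crystal, (0, 0, 1), offset, params,
                                  radius=14.0)
            assert abs(t.e_att) <= abs(t.e_latt) + 1e-9


class TestTerminationScan:
    def test_default_step_enumerates_ten_offsets(self, bilayer_crystal, params):
        scan = scan_terminations(bilayer_crystal, (0, 0, 1), params, radius=12.0)
        assert len(scan.terminations) == 10
        assert [t.offset for t in scan.terminations] == pytest.approx(
            [0.1 * i for i in range(10)])

    def test_selection_matches_fine_scan_oracle(self, bilayer_crystal, params):
        coarse = scan_terminations(bilayer_crystal, (0, 0, 1), params,
                                   step=0.1, radius=12.0)
        fine = scan_terminations(bilayer_crystal, (0, 0, 1), params,
                                 step=0.01, radius=12.0)
        assert len(fine.terminations) == 100
        assert coarse.selected.e_att == pytest.approx(fine.selected.e_att,
                                                      rel=1e-9)

    def test_uneven_step_rejected(self, bilayer_crystal, params):
        with pytest.raises(ValueError):
            scan_terminations(bilayer_crystal, (0, 0, 1), params, step=0.3)


class TestBFDH:
    def test_cubic_cell_with_cyclic_symmetry_groups_100_family(self):
        ops = [SymOp.identity(), SymOp.from_xyz("z,x,y"), SymOp.from_xyz("y,z,x")]
        s = CrystalStructure(UnitCell(5, 5, 5),
                             [AtomSite("C", "C1", np.zeros(3), 0.0, "C_3")], ops)
        faces = bfdh_faces(s, 1)
        members = {m.as_tuple() for m in faces[0].family}
        assert members == {(1, 0, 0), (0, 1, 0), (0, 0, 1)}
        assert faces[0].d_eff == pytest.approx(5.0)

    def test_orthorhombic_ranking_follows_axis_lengths(self):
        s = CrystalStructure(UnitCell(3, 4, 5),
                             [AtomSite("C", "C1", np.zeros(3), 0.0, "C_3")])
        ranked = [f.miller.as_tuple() for f in bfdh_faces(s, 27)]
        # the three axis faces rank by descending cell edge: d = 5, 4, 3
        assert ranked[0] == (0, 0, 1)
        assert ranked.index((0, 0, 1)) < ranked.index((0, 1, 0)) < ranked.index((1, 0, 0))

    def test_screw_axis_demotes_010_to_020_spacing(self):
        cell = UnitCell(4.783, 21.54, 7.7599, 90, 105.911, 90)
        ops = [SymOp.identity(), SymOp.from_xyz("-x,y+1/2,-z")]
        s = CrystalStructure(cell, [AtomSite("C", "C1",
                                             np.array([0.1, 0.2, 0.3]), 0.0, "C_3")], ops)
        faces = bfdh_faces(s, 5)
        by_index = {f.miller.as_tuple(): f.d_eff for f in faces}
        assert by_index[(0, 1, 0)] == pytest.approx(21.54 / 2, rel=1e-6)
        # monohydrate-like cell: (010) still dominates (100) and (001)
        assert faces[0].miller.as_tuple() == (0, 1, 0)
        assert by_index[(0, 1, 0)] > d_spacing(cell, (1, 0, 0))
        assert by_index[(0, 1, 0)] > d_spacing(cell, (0, 0, 1))


class TestBuildSlab:
    def test_single_atom_cell_slab_counts(self):
        s, params = sc_lj(4.0)
        p = toy_params(s.toy_types, cutoff=5.0)
        scan = scan_terminations(s, (0, 0, 1), p, radius=8.0)
        one = build_slab(s, (0, 0, 1), scan.selected, (2, 2), 1)
        assert one.natoms == 4
        two = build_slab(s, (0, 0, 1), scan.selected, (2, 2), 2)
        assert two.natoms == 8
        assert one.area == pytest.approx(64.0)

    def test_probe_slab_is_one_molecular_layer_thick(self, bilayer_crystal, params):
        scan = scan_terminations(bilayer_crystal, (0, 0, 1), params, radius=12.0)
        probe = build_slab(bilayer_crystal, (0, 0, 1), scan.selected, (2, 2), 1)
        z = probe.body.xyz[:, 2]
        assert z.max() - z.min() <= probe.d_hkl + 1e-9
        # centroid assignment never splits a diatomic: whole molecules only
        assert probe.natoms % 2 == 0

    def test_invalid_layers_rejected(self, bilayer_crystal, params):
        scan = scan_terminations(bilayer_crystal, (0, 0, 1), params, radius=12.0)
        with pytest.raises(StructureError):
            build_slab(bilayer_crystal, (0, 0, 1), scan.selected, (2, 2), 0)


def flat_slab(spacing=0.75, n=14, element="C", z=0.0):
    xs = np.arange(n) * spacing
    pts = np.array([(x, y, z) for x in xs for y in xs])
    body = Body([element] * len(pts), pts, charges=np.zeros(len(pts)),
                types=["C_3"] * len(pts), label="flat")
    dummy = Termination(MillerIndex(0, 0, 1), 0.0, 0.0, 0.0, 0.0)
    return Slab(body, MillerIndex(0, 0, 1), dummy, (1, 1), 1,
                area=(xs[-1]) ** 2, d_hkl=1.0, top_z=z)


class TestRugosity:
    def test_flat_dense_lattice_is_nearly_smooth(self):
        assert rugosity(flat_slab(), 0.2) == pytest.approx(1.0, abs=0.05)

    def test_two_level_step_matches_analytic_ratio(self):
        # dense square lattice, lower half at z=0, upper half at z=H;
        # analytic profile: flat tops + quarter-circle shoulder + vertical
        # drop of (H - r) spread over one grid cell
        spacing, n, H = 0.25, 40, 3.0
        r = 1.70  # carbon vdW radius
        xs = np.arange(n) * spacing
        pts = np.array([(x, y, H if x >= xs[n // 2] else 0.0)
                        for x in xs for y in xs])
        body = Body(["C"] * len(pts), pts, charges=np.zeros(len(pts)),
                    types=["C_3"] * len(pts), label="step")
        dummy = Termination(MillerIndex(0, 0, 1), 0.0, 0.0, 0.0, 0.0)
        slab = Slab(body, MillerIndex(0, 0, 1), dummy, (1, 1), 1,
                    area=xs[-1] ** 2, d_hkl=1.0, top_z=H)
        lx = ly = xs[-1]
        extra_per_length = (H - r) + (math.pi / 2 - 1) * r
        expected = (lx * ly + ly * extra_per_length) / (lx * ly)
        assert rugosity(slab, 0.1) == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("spacing", [0.5, 1.0, 2.0])
    def test_rugosity_at_least_one(self, spacing):
        assert rugosity(flat_slab(spacing=spacing), 0.25) >= 1.0

    def test_invalid_resolution_rejected(self):
        with pytest.raises(ValueError):
            rugosity(flat_slab(), 0.0)
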