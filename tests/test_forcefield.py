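import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from synthgrid.fixtures import make_ionic_triplet, toy_params
from synthgrid.forcefield import (
    Atom,
    Body,
    EnergyBreakdown,
    FFParams,
    ForceFieldError,
    ParameterizationError,
    assign_types_and_charges,
    body_body_energy,
    pair_energy,
)

from conftest import random_charged_body
from oracles import pairwise_energy_loop


def water_body():
    o = np.array([0.0, 0.0, 0.0])
    h1 = np.array([0.757, 0.0, 0.586])
    h2 = np.array([-0.757, 0.0, 0.586])
    return Body(["O", "H", "H"], np.vstack([o, h1, h2]),
                bonds=[(0, 1), (0, 2)], label="water")


class TestTyping:
    def test_water_typed_as_sp3_acceptor_with_donor_hydrogens(self):
        w = assign_types_and_charges(water_body())
        assert w.types == ["O_3", "H__HB", "H__HB"]
        assert w.hb_roles == ["acceptor", "donor_h", "donor_h"]

    def test_three_coordinate_carbon_is_sp2(self):
        xyz = [[0, 0, 0], [1.4, 0, 0], [-0.7, 1.2, 0], [-0.7, -1.2, 0]]
        b = Body(["C", "C", "C", "C"], xyz, bonds=[(0, 1), (0, 2), (0, 3)])
        typed = assign_types_and_charges(b)
        assert typed.types[0] == "C_2"

    def test_ionic_triplet_formal_charges_sum_to_zero(self):
        s = make_ionic_triplet()
        exp = s.expand_p1()
        assert len(exp.units) == 3
        assert float(np.sum(exp.charges)) == pytest.approx(0.0, abs=1e-12)

    def test_formal_charge_override_per_unit(self):
        b = Body(["N", "N"], [[0, 0, 0], [0, 0, 4.0]], units=[[0], [1]])
        typed = assign_types_and_charges(b, formal_charges=[1.0, -1.0])
        assert typed.charges[0] == pytest.approx(1.0)
        assert typed.charges.sum() == pytest.approx(0.0)

    def test_unknown_element_raises_parameterization_error(self):
        b = Body(["Xe"], [[0, 0, 0]])
        with pytest.raises(ParameterizationError, match="Xe"):
            assign_types_and_charges(b)

    def test_charge_table_missing_label_raises(self):
        b = Body(["N"], [[0, 0, 0]])
        with pytest.raises(ForceFieldError, match="N"):
            assign_types_and_charges(b, charge_scheme="table", charge_table={"O": -1.0})

    def test_gasteiger_water_polarity(self):
        w = assign_types_and_charges(water_body())
        assert w.charges[0] < -0.1          # oxygen negative
        assert all(q > 0 for q in w.charges[1:])
        assert float(w.charges.sum()) == pytest.approx(0.0, abs=1e-12)


class TestPairEnergy:
    def test_lj_minimum_is_minus_well_depth(self):
        params = toy_params({"LJ": (0.7, 3.0)})
        a = Atom("Ar", (0, 0, 0), 0.0, "LJ")
        b = Atom("Ar", (3.0, 0, 0), 0.0, "LJ")
        e = pair_energy(a, b, params)
        assert e.total == pytest.approx(-0.7, rel=1e-12)
        assert e.electrostatic == 0.0

    def test_all_components_zero_beyond_cutoff(self):
        params = toy_params({"LJ": (0.7, 3.0)}, cutoff=10.0)
        a = Atom("Ar", (0, 0, 0), 1.0, "LJ")
        b = Atom("Ar", (20.0, 0, 0), -1.0, "LJ")
        e = pair_energy(a, b, params)
        assert (e.dispersive, e.electrostatic, e.hbond) == (0.0, 0.0, 0.0)

    def test_unit_charges_at_coulomb_reference_distance(self):
        # k_e / 3.320637 = 100 exactly by choice of distance; vdW off via D0=0
        params = toy_params({"Q0": (0.0, 3.0)})
        a = Atom("Na", (0, 0, 0), 1.0, "Q0")
        b = Atom("Cl", (3.320637, 0, 0), -1.0, "Q0")
        e = pair_energy(a, b, params)
        assert e.electrostatic == pytest.approx(-100.0, abs=1e-9)
        assert e.dispersive == 0.0

    def test_zero_separation_is_singular(self):
        params = toy_params()
        a = Atom("N", (0, 0, 0), 0.0, "TOY_A")
        with pytest.raises(ForceFieldError):
            pair_energy(a, a, params)


class TestBodyBodyEnergy:
    def test_single_atom_bodies_reduce_to_pair_energy(self, params):
        a = Body(["N"], [[0, 0, 0]], charges=[0.1], types=["TOY_A"])
        b = Body(["O"], [[3.3, 0, 0]], charges=[-0.1], types=["TOY_B"])
        e = body_body_energy(a, b, params)
        ref = pair_energy(a.atom(0), b.atom(0), params)
        assert e.total == pytest.approx(ref.total, rel=1e-12)

    def test_symmetric_in_argument_order(self, params):
        rng = np.random.default_rng(7)
        a = random_charged_body(rng, 4, "A")
        b = random_charged_body(rng, 6, "B").transformed(translation=[6, 0, 0])
        ea = body_body_energy(a, b, params)
        eb = body_body_energy(b, a, params)
        assert ea.total == pytest.approx(eb.total, rel=1e-12)
        assert ea.dispersive == pytest.approx(eb.dispersive, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_pairwise_double_loop(self, params, seed):
        rng = np.random.default_rng(seed)
        a = random_charged_body(rng, 5, "A")
        b = random_charged_body(rng, 7, "B").transformed(translation=[5.5, 0.5, -0.5])
        e = body_body_energy(a, b, params)
        disp, elec, hb = pairwise_energy_loop(a, b, params)
        assert e.dispersive == pytest.approx(disp, rel=1e-10, abs=1e-12)
        assert e.electrostatic == pytest.approx(elec, rel=1e-10, abs=1e-12)
        assert e.hbond == pytest.approx(hb, rel=1e-10, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_rigid_motion_invariance(self, params, seed):
        from synthgrid.grid_search import euler_zyx_matrix
        rng = np.random.default_rng(100 + seed)
        a = random_charged_body(rng, 4, "A")
        b = random_charged_body(rng, 5, "B").transformed(translation=[6, 0, 0])
        e0 = body_body_energy(a, b, params)
        rot = euler_zyx_matrix(*rng.uniform(0, 360, 3))
        shift = rng.uniform(-20, 20, 3)
        a2 = a.transformed(rotation=rot, pivot=[0, 0, 0], translation=shift)
        b2 = b.transformed(rotation=rot, pivot=[0, 0, 0], translation=shift)
        e1 = body_body_energy(a2, b2, params)
        assert e1.total == pytest.approx(e0.total, rel=1e-9)
        assert e1.hbond == pytest.approx(e0.hbond, rel=1e-9, abs=1e-12)

    def test_total_equals_component_sum_on_every_evaluation(self, params):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = random_charged_body(rng, 3, "A")
            b = random_charged_body(rng, 4, "B").transformed(
                translation=rng.uniform(4, 8, 3))
            e = body_body_energy(a, b, params)
            assert e.total == pytest.approx(
                e.dispersive + e.electrostatic + e.hbond, abs=1e-9)
            assert e.polar == pytest.approx(e.electrostatic + e.hbond, abs=1e-12)

    def test_neutral_dimer_decays_monotonically_beyond_minimum(self):
        params = toy_params({"LJ": (1.0, 3.0)}, cutoff=12.0)
        a = Body(["Ar"], [[0, 0, 0]], charges=[0.0], types=["LJ"])
        prev = None
        for r in np.arange(3.0, 12.0, 0.25):
            b = Body(["Ar"], [[r, 0, 0]], charges=[0.0], types=["LJ"])
            e = body_body_energy(a, b, params).total
            if prev is not None:
                assert e >= prev - 1e-15
            assert e < 0
            prev = e
        far = Body(["Ar"], [[24.0, 0, 0]], charges=[0.0], types=["LJ"])
        assert body_body_energy(a, far, params).total == 0.0

    def test_untyped_atom_is_identified(self, params):
        a = Body(["N"], [[0, 0, 0]], charges=[0.0], types=[None])
        b = Body(["N"], [[3, 0, 0]], charges=[0.0], types=["TOY_A"])
        with pytest.raises(ForceFieldError, match="atom 0"):
            body_body_energy(a, b, params)


class TestHydrogenBond:
    def test_linear_geometry_gives_attractive_12_10_well(self, params):
        # donor N-H pointing at an acceptor O, D...A at the well distance
        d = params.hb_r0
        donor = Body(["N", "H"], [[0, 0, 0], [0, 0, 1.0]],
                     charges=[0.0, 0.0], types=["TOY_B", "TOY_H"],
                     bonds=[(0, 1)], hb_roles=["none", "donor_h"])
        acceptor = Body(["O"], [[0, 0, d]], charges=[0.0], types=["TOY_B"],
                        hb_roles=["acceptor"])
        e = body_body_energy(donor, acceptor, params)
        assert e.hbond == pytest.approx(-params.hb_depth, rel=1e-9)

    def test_right_angle_geometry_has_no_hbond(self, params):
        donor = Body(["N", "H"], [[0, 0, 0], [0, 0, 1.0]],
                     charges=[0.0, 0.0], types=["TOY_B", "TOY_H"],
                     bonds=[(0, 1)], hb_roles=["none", "donor_h"])
        acceptor = Body(["O"], [[2.75, 0, 1.0]], charges=[0.0], types=["TOY_B"],
                        hb_roles=["acceptor"])
        e = body_body_energy(donor, acceptor, params)
        assert e.hbond == 0.0

    def test_beyond_hb_cutoff_no_hbond(self, params):
        donor = Body(["N", "H"], [[0, 0, 0], [0, 0, 1.0]],
                     charges=[0.0, 0.0], types=["TOY_B", "TOY_H"],
                     bonds=[(0, 1)], hb_roles=["none", "donor_h"])
        acceptor = Body(["O"], [[0, 0, params.hb_cutoff + 0.5]], charges=[0.0],
                        types=["TOY_B"], hb_roles=["acceptor"])
        assert body_body_energy(donor, acceptor, params).hbond == 0.0


class TestFFParams:
    def test_packaged_table_loads_common_organic_types(self):
        p = FFParams.default()
        for t in ("H_", "C_3", "N_3", "O_3", "S_3"):
            d0, r0 = p.lookup(t)
            assert d0 > 0 and r0 > 0

    def test_missing_type_raises(self):
        with pytest.raises(ParameterizationError, match="NOPE"):
            FFParams.default().lookup("NOPE")

    def test_invalid_dielectric_rejected(self):
        with pytest.raises(ValueError):
            FFParams(vdw={"X": (0.1, 3.0)}, dielectric=0.5)
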