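"""Deterministic toy crystal structures for testing and demonstration.

Real studies of powder blends start from experimentally determined crystal
structures of the blend components. These generators provide small synthetic
stand-ins with the same *structural features* -- P1 and P2_1 cells, neutral
molecular crystals, an ionic multi-body asymmetric unit, a hydrate-like cell
with a small bent molecule -- so the whole pipeline (symmetry expansion, slab
cutting, grid search, blend statistics) runs without any external database.
They use analytically tractable lattices (simple cubic Lennard-Jones,
rock salt) wherever a hand-computable oracle is wanted.

All generators are pure functions of their arguments; regenerating a
structure gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal_structures import AtomSite, CrystalStructure, SymOp, UnitCell
from .forcefield import FFParams

__all__ = [
    "ToySpec",
    "make_structure",
    "make_sc_lj",
    "make_rocksalt",
    "make_diatomic_molecular",
    "make_hydrate_like",
    "make_ionic_triplet",
    "toy_params",
    "TOY_VDW",
]

#: vdW parameters for the toy atom types (D0 kcal/mol, R0 Angstrom).
TOY_VDW = {
    "LJ": (1.0, 1.0),          # rescaled per fixture via with_types
    "ION": (0.01, 3.2),
    "TOY_A": (0.2, 3.5),
    "TOY_B": (0.1, 3.0),
    "TOY_H": (0.01, 2.8),
}


def toy_params(extra=None, **overrides) -> FFParams:
    """Force-field parameters covering the toy types (plus the defaults)."""
    table = dict(TOY_VDW)
    if extra:
        table.update(extra)
    return FFParams.default(**overrides).with_types(table)


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a toy crystal; recorded in the provenance of outputs."""

    kind: str                      # sc-lj | rocksalt | diatomic-molecular | hydrate-like | ionic-triplet
    a: float = 4.0
    d0: float = 1.0
    r0: float = 1.0
    q: float = 0.0
    bond_length: float = 1.1
    p21: bool = False
    polar: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.r0 <= 0 or self.bond_length <= 0:
            raise ValueError("toy-structure dimensions must be positive")


def make_structure(spec: ToySpec) -> CrystalStructure:
    if spec.kind == "sc-lj":
        return make_sc_lj(spec.a, spec.d0, spec.r0)
    if spec.kind == "rocksalt":
        return make_rocksalt(spec.a, abs(spec.q) or 1.0)
    if spec.kind == "diatomic-molecular":
        cell = UnitCell(spec.a, spec.a, spec.a)
        charges = (spec.q, -spec.q) if spec.polar else (0.0, 0.0)
        return make_diatomic_molecular(cell, spec.bond_length, charges, p21=spec.p21)
    if spec.kind == "hydrate-like":
        return make_hydrate_like(spec.a)
    if spec.kind == "ionic-triplet":
        return make_ionic_triplet(spec.a)
    raise ValueError(f"unknown toy kind {spec.kind!r}")


def make_sc_lj(a: float, d0: float = 1.0, r0: float | None = None) -> CrystalStructure:
    """Simple-cubic P1 crystal with one neutral Lennard-Jones atom per cell.

    With ``a == r0`` and a nearest-neighbor-only cutoff the lattice energy is
    exactly -3 D0 per atom (six neighbors at the potential minimum, half
    counted), which makes this the analytic substrate for lattice-sum and
    attachment-energy checks. The atom is typed ``LJ``; pair D0/R0 come from
    the parameter table (see :func:`toy_params`).
    """
    if a <= 0:
        raise ValueError("lattice constant must be positive")
    cell = UnitCell(a, a, a)
    site = AtomSite("Ar", "LJ1", np.zeros(3), charge=0.0, ff_type="LJ")
    structure = CrystalStructure(cell, [site], spacegroup="P 1", bond_scale=0.0)
    # pair parameters travel with the structure; feed them to toy_params(extra=...)
    structure.toy_types = {"LJ": (d0, r0 if r0 is not None else a)}
    return structure


def make_rocksalt(a_nn: float, q: float = 1.0) -> CrystalStructure:
    """Rock-salt toy crystal: two interpenetrating fcc sublattices of +/- q.

    ``a_nn`` is the nearest-neighbor (cation--anion) distance; the cubic cell
    edge is ``2 * a_nn``. The cell is charge neutral, each ion is its own
    molecular unit, and the electrostatic lattice sum gives the Madelung
    constant 1.7476 for direct summation over neutral shells of whole cells.
    """
    if a_nn <= 0 or q <= 0:
        raise ValueError("a_nn and q must be positive")
    cell = UnitCell(2 * a_nn, 2 * a_nn, 2 * a_nn)
    cation = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    anion = [(0.5, 0, 0), (0, 0.5, 0), (0, 0, 0.5), (0.5, 0.5, 0.5)]
    sites = [AtomSite("Na", f"NA{i + 1}", np.array(f), charge=q, ff_type="ION")
             for i, f in enumerate(cation)]
    sites += [AtomSite("Cl", f"CL{i + 1}", np.array(f), charge=-q, ff_type="ION")
              for i, f in enumerate(anion)]
    return CrystalStructure(cell, sites, spacegroup="P 1", bond_scale=0.0)


def make_diatomic_molecular(
    cell: UnitCell,
    bond_length: float = 1.1,
    charges: tuple[float, float] = (0.0, 0.0),
    p21: bool = False,
    tilt: float = 0.0,
) -> CrystalStructure:
    """Molecular crystal with one rigid diatomic per asymmetric unit.

    The molecule lies (almost) along +z, centered at (1/4, 1/4, 1/4) of the
    cell so that slicing planes never cut through it ambiguously. The polar
    variant (nonzero ``charges``) places a positive H-like end and a negative
    N-like end, giving hydrogen-bond donor/acceptor machinery something to
    act on. With ``p21=True`` a second, screw-related molecule per cell is
    generated by the operator (-x, y+1/2, -z).
    """
    dz = bond_length / (2 * cell.c)
    dx = tilt / (2 * cell.a)
    center = np.array([0.25, 0.25, 0.25])
    polar = charges != (0.0, 0.0)
    el_top, el_bot = ("H", "N") if polar else ("N", "N")
    t_top, t_bot = ("TOY_H", "TOY_B") if polar else ("TOY_A", "TOY_A")
    sites = [
        AtomSite(el_top, "A1", center + [dx, 0, dz], charge=charges[0], ff_type=t_top),
        AtomSite(el_bot, "A2", center - [dx, 0, dz], charge=charges[1], ff_type=t_bot),
    ]
    ops = [SymOp.identity()]
    sg = "P 1"
    if p21:
        ops.append(SymOp.from_xyz("-x,y+1/2,-z"))
        sg = "P 21"
    return CrystalStructure(cell, sites, ops, spacegroup=sg)


def make_hydrate_like(a: float = 6.0) -> CrystalStructure:
    """P1 cell holding one diatomic 'host' molecule plus one bent water.

    Mimics a monohydrate: the water oxygen accepts and its hydrogens donate,
    so hydrogen-bond pathways between molecular units are exercised. Two
    molecular units per cell.
    """
    cell = UnitCell(a, a, a)
    # host diatomic along z at cell origin corner
    sites = [
        AtomSite("N", "M1", np.array([0.2, 0.2, 0.15]), charge=-0.2, ff_type="TOY_B"),
        AtomSite("H", "M2", np.array([0.2, 0.2, 0.15 + 1.0 / a]), charge=0.2, ff_type="TOY_H"),
    ]
    # bent water near the cell center (O-H ~ 0.96 A, H-O-H ~ 104.5 deg)
    o = np.array([0.6, 0.6, 0.55]) * a
    h1 = o + np.array([0.757, 0.0, 0.586])
    h2 = o + np.array([-0.757, 0.0, 0.586])
    for lbl, el, pos, q in (("OW", "O", o, -0.66), ("HW1", "H", h1, 0.33), ("HW2", "H", h2, 0.33)):
        sites.append(AtomSite(el, lbl, pos / a, charge=q, ff_type=None))
    return CrystalStructure(cell, sites, spacegroup="P 1")


def make_ionic_triplet(a: float = 7.0) -> CrystalStructure:
    """P1 cell with a tri-ionic asymmetric unit: two +1 cations, one -2 anion.

    Emulates a salt of a protonated base with a divalent counter-ion (the
    2:1 cation:anion motif of sulfate salts): three molecular units per cell,
    zero net cell charge.
    """
    cell = UnitCell(a, a, a)
    sites = [
        AtomSite("N", "CAT1", np.array([0.15, 0.15, 0.2]), charge=0.9, ff_type="TOY_B"),
        AtomSite("H", "CAT1H", np.array([0.15, 0.15, 0.2 + 1.0 / a]), charge=0.1, ff_type="TOY_H"),
        AtomSite("N", "CAT2", np.array([0.65, 0.65, 0.7]), charge=0.9, ff_type="TOY_B"),
        AtomSite("H", "CAT2H", np.array([0.65, 0.65, 0.7 + 1.0 / a]), charge=0.1, ff_type="TOY_H"),
        AtomSite("S", "AN1", np.array([0.4, 0.65, 0.25]), charge=-2.0, ff_type="S_3"),
    ]
    return CrystalStructure(cell, sites, spacegroup="P 1")
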