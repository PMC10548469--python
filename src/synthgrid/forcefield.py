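"""Dreiding-style nonbonded force field for rigid-body interaction energies.

The energy between two rigid bodies (molecules, dimers or surface slabs) is a
sum over inter-body atom pairs of three terms:

* dispersive: a 12-6 Lennard-Jones potential
  ``E = D0 * [(R0/r)^12 - 2 (R0/r)^6]`` with per-type well depth ``D0``
  (kcal/mol) and equilibrium distance ``R0`` (Angstrom); unlike parameters are
  combined with a geometric mean on ``D0`` and (by default) an arithmetic mean
  on ``R0``;
* electrostatic: Coulomb's law ``E = k_e q_i q_j / (eps * r)`` with
  ``k_e = 332.0637 kcal*A/(mol*e^2)``;
* hydrogen bond: the Dreiding 12-10 term
  ``E = D_hb * [5 (R_hb/r_DA)^12 - 6 (R_hb/r_DA)^10] * cos^4(theta_DHA)``
  evaluated on the donor--acceptor distance for D-H...A triples that span the
  two bodies; where it applies it replaces the plain Lennard-Jones term of the
  donor/acceptor heavy-atom pair.

All terms are truncated to zero at the nonbond cutoff. Component sums use
compensated (exact) summation so that an energy is independent of the order in
which pairs are enumerated; two code paths that enumerate the same pairs give
bit-identical totals.

Units are kcal/mol and Angstrom throughout; conversion to kJ happens only at
reporting time (see :mod:`synthgrid.blend_analysis`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .periodic import normalize_element, vdw_radius

KCAL_COULOMB_CONSTANT = 332.0637  # kcal*Angstrom/(mol*e^2)

__all__ = [
    "Atom",
    "Body",
    "EnergyBreakdown",
    "FFParams",
    "ForceFieldError",
    "ParameterizationError",
    "assign_types_and_charges",
    "body_body_energy",
    "hbond_energy",
    "pair_energy",
]


class ForceFieldError(ValueError):
    """Raised for invalid force-field input (untyped atoms, zero separations...)."""


class ParameterizationError(ForceFieldError):
    """Raised when an atom cannot be assigned force-field parameters."""


# --------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class FFParams:
    """Force-field parameter set.

    ``vdw`` maps an atom type to ``(D0, R0)``. ``r0_mixing`` selects the
    combination rule for unlike ``R0`` ("arithmetic" or "geometric"); ``D0``
    always mixes geometrically.
    """

    vdw: Mapping[str, tuple[float, float]]
    hb_depth: float = 9.5        # kcal/mol
    hb_r0: float = 2.75          # Angstrom, donor--acceptor
    hb_cutoff: float = 4.5       # Angstrom, donor--acceptor
    dielectric: float = 1.0
    coulomb_k: float = KCAL_COULOMB_CONSTANT
    cutoff: float = 15.0         # Angstrom, plain truncation
    r0_mixing: str = "arithmetic"

    def __post_init__(self) -> None:
        if self.dielectric < 1.0:
            raise ValueError("dielectric constant must be >= 1")
        if self.r0_mixing not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown R0 mixing rule {self.r0_mixing!r}")
        for t, (d0, r0) in self.vdw.items():
            if d0 < 0 or r0 <= 0:
                raise ValueError(f"invalid vdW parameters for type {t!r}: D0={d0}, R0={r0}")

    @classmethod
    def default(cls, **overrides) -> "FFParams":
        """Packaged Dreiding-style parameter table."""
        text = resources.files("synthgrid.data").joinpath("dreiding_vdw.csv").read_text()
        return cls(vdw=_parse_vdw_table(text.splitlines()), **overrides)

    @classmethod
    def from_file(cls, path, **overrides) -> "FFParams":
        with open(path) as fh:
            return cls(vdw=_parse_vdw_table(fh), **overrides)

    def with_types(self, extra: Mapping[str, tuple[float, float]], **overrides) -> "FFParams":
        merged = dict(self.vdw)
        merged.update(extra)
        return replace(self, vdw=merged, **overrides)

    def lookup(self, ff_type: str) -> tuple[float, float]:
        try:
            return self.vdw[ff_type]
        except KeyError:
            raise ParameterizationError(
                f"no vdW parameters for atom type {ff_type!r}"
            ) from None


def _parse_vdw_table(lines: Iterable[str]) -> dict[str, tuple[float, float]]:
    table: dict[str, tuple[float, float]] = {}
    for row in csv.reader(lines):
        if not row or row[0].lstrip().startswith("#"):
            continue
        if len(row) != 3:
            raise ValueError(f"malformed vdW table row: {row!r}")
        table[row[0].strip()] = (float(row[1]), float(row[2]))
    if not table:
        raise ValueError("empty vdW parameter table")
    return table


# --------------------------------------------------------------------------
# bodies


@dataclass(frozen=True)
class Atom:
    """A single typed atom; view into a :class:`Body` or free-standing."""

    element: str
    xyz: tuple[float, float, float]
    charge: float | None = None
    ff_type: str | None = None
    hb_role: str = "none"  # "donor_h" | "acceptor" | "none"


class Body:
    """A finite rigid collection of atoms (molecule, dimer or slab).

    Coordinates are Cartesian Angstrom. ``bonds`` is intra-body connectivity
    (used for typing and for locating donor hydrogens); ``units`` partitions
    atom indices into molecular units. Energy evaluation only ever considers
    inter-body pairs, so intra-body terms never arise.
    """

    def __init__(
        self,
        elements: Sequence[str],
        xyz: np.ndarray,
        charges: Sequence[float] | None = None,
        types: Sequence[str | None] | None = None,
        bonds: Sequence[tuple[int, int]] = (),
        units: Sequence[Sequence[int]] | None = None,
        label: str = "body",
        hb_roles: Sequence[str] | None = None,
    ) -> None:
        self.elements = [normalize_element(e) for e in elements]
        self.xyz = np.asarray(xyz, dtype=float).reshape(len(self.elements), 3)
        n = len(self.elements)
        if n < 1:
            raise ValueError("a body needs at least one atom")
        self.charges = None if charges is None else np.asarray(charges, dtype=float)
        self.types: list[str | None] = list(types) if types is not None else [None] * n
        self.bonds = [(min(i, j), max(i, j)) for i, j in bonds]
        self.units = [list(u) for u in units] if units is not None else [list(range(n))]
        self.label = label
        self.hb_roles = list(hb_roles) if hb_roles is not None else ["none"] * n

    # -- basic geometry ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def natoms(self) -> int:
        return len(self.elements)

    def centroid(self) -> np.ndarray:
        return self.xyz.mean(axis=0)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.xyz.min(axis=0), self.xyz.max(axis=0)

    def vdw_radii(self) -> np.ndarray:
        return np.array([vdw_radius(e) for e in self.elements])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    pivot: np.ndarray | None = None) -> "Body":
        """Rigid motion: rotate about ``pivot`` (default: centroid), then translate."""
        xyz = self.xyz
        if rotation is not None:
            p = self.centroid() if pivot is None else np.asarray(pivot, float)
            xyz = (xyz - p) @ np.asarray(rotation, float).T + p
        if translation is not None:
            xyz = xyz + np.asarray(translation, float)
        return self._with_xyz(xyz)

    def _with_xyz(self, xyz: np.ndarray) -> "Body":
        clone = Body(self.elements, xyz, self.charges, self.types, self.bonds,
                     self.units, self.label, self.hb_roles)
        return clone

    def atom(self, i: int) -> Atom:
        q = None if self.charges is None else float(self.charges[i])
        return Atom(self.elements[i], tuple(self.xyz[i]), q, self.types[i], self.hb_roles[i])

    # -- typing state ------------------------------------------------------

    def require_typed(self) -> None:
        for i, t in enumerate(self.types):
            if t is None:
                raise ForceFieldError(
                    f"atom {i} ({self.elements[i]}) of body {self.label!r} has no force-field type"
                )
        if self.charges is None or not np.all(np.isfinite(self.charges)):
            raise ForceFieldError(f"body {self.label!r} has missing or non-finite charges")

    def neighbor_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(len(self))]
        for i, j in self.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs

    def donor_triples(self) -> list[tuple[int, int]]:
        """(heavy donor index, hydrogen index) pairs for every donor H."""
        nbrs = self.neighbor_lists()
        out = []
        for h, role in enumerate(self.hb_roles):
            if role != "donor_h":
                continue
            heavies = [j for j in nbrs[h] if self.elements[j] != "H"]
            if heavies:
                out.append((heavies[0], h))
        return out

    def acceptor_indices(self) -> list[int]:
        return [i for i, role in enumerate(self.hb_roles) if role == "acceptor"]


# --------------------------------------------------------------------------
# atom typing and charges

_HB_ELEMENTS = {"N", "O", "F"}

# Gasteiger PEOE electronegativity polynomials chi(q) = a + b q + c q^2,
# keyed by (element, hybridization); hybridization "" matches any.
_PEOE = {
    ("H", ""): (7.17, 6.24, -0.56),
    ("C", "3"): (7.98, 9.18, 1.88),
    ("C", "2"): (8.79, 9.32, 1.51),
    ("C", "R"): (8.79, 9.32, 1.51),
    ("C", "1"): (10.39, 9.45, 0.73),
    ("N", "3"): (11.54, 10.82, 1.36),
    ("N", "2"): (12.87, 11.15, 0.85),
    ("N", "R"): (12.87, 11.15, 0.85),
    ("N", "1"): (15.68, 11.70, -0.27),
    ("O", "3"): (14.18, 12.92, 1.39),
    ("O", "2"): (17.07, 13.79, 0.47),
    ("O", "R"): (17.07, 13.79, 0.47),
    ("F", ""): (14.66, 13.85, 2.31),
    ("Cl", ""): (11.00, 9.69, 1.35),
    ("Br", ""): (10.08, 8.47, 1.16),
    ("I", ""): (9.90, 7.96, 0.96),
    ("S", ""): (10.14, 9.13, 1.38),
    ("P", ""): (8.90, 8.24, 0.96),
    ("B", ""): (5.98, 6.82, 1.60),
}
_PEOE_H_CATION = 20.02  # chi+ used in the transfer denominator for hydrogen


def _dreiding_type(element: str, n_neighbors: int) -> str:
    """Hybridization-style Dreiding type from element + coordination number."""
    if element == "H":
        return "H_"
    if element == "C":
        return {4: "C_3", 3: "C_2", 2: "C_1", 1: "C_1"}.get(n_neighbors, "C_3")
    if element == "N":
        return {4: "N_3", 3: "N_3", 2: "N_2", 1: "N_1"}.get(n_neighbors, "N_3")
    if element == "O":
        return "O_3" if n_neighbors >= 2 else ("O_2" if n_neighbors == 1 else "O_3")
    single = {"F": "F_", "Cl": "Cl_", "Br": "Br_", "I": "I_", "S": "S_3",
              "P": "P_3", "B": "B_3", "Na": "Na_", "K": "K_", "Ca": "Ca_",
              "Mg": "Mg_", "Zn": "Zn_"}
    if element in single:
        return single[element]
    raise ParameterizationError(f"no Dreiding-style type rule for element {element!r}")


def _peoe_params(element: str, ff_type: str) -> tuple[float, float, float]:
    hyb = ff_type.split("_")[-1] if "_" in ff_type else ""
    for key in ((element, hyb), (element, "")):
        if key in _PEOE:
            return _PEOE[key]
    # fallback: treat like sp3 carbon (soft, nearly neutral element)
    return _PEOE[("C", "3")]


def gasteiger_charges(body: Body, n_iter: int = 8) -> np.ndarray:
    """Iterative partial-equalization (PEOE) charges from connectivity.

    All bonds are treated as single bonds; hybridization enters through the
    electronegativity polynomial chosen for each atom's assigned type.
    """
    n = len(body)
    q = np.zeros(n)
    abc = [_peoe_params(body.elements[i], body.types[i] or "") for i in range(n)]
    chi_plus = np.array([
        _PEOE_H_CATION if body.elements[i] == "H" else sum(abc[i]) for i in range(n)
    ])
    damp = 1.0
    for _ in range(n_iter):
        damp *= 0.5
        chi = np.array([a + b * qi + c * qi * qi for (a, b, c), qi in zip(abc, q)])
        dq = np.zeros(n)
        for i, j in body.bonds:
            if chi[j] > chi[i]:
                t = (chi[j] - chi[i]) / chi_plus[i] * damp
                dq[i] += t
                dq[j] -= t
            elif chi[i] > chi[j]:
                t = (chi[i] - chi[j]) / chi_plus[j] * damp
                dq[j] += t
                dq[i] -= t
        q += dq
    return q


def assign_types_and_charges(
    body: Body,
    charge_scheme: str = "gasteiger",
    charge_table: Mapping[str, float] | None = None,
    formal_charges: Sequence[float] | None = None,
) -> Body:
    """Assign Dreiding-style atom types, hydrogen-bond roles and charges.

    ``charge_scheme``:

    * ``"gasteiger"`` -- built-in PEOE from connectivity (default);
    * ``"table"`` -- look charges up by element symbol in ``charge_table``;
    * ``"zero"`` -- all charges zero (pure-dispersive studies).

    ``formal_charges`` gives one net charge per molecular unit (e.g. +1, +1,
    -2 for a di-cation/sulfate asymmetric unit); after the scheme runs, each
    unit's charges are shifted uniformly so the unit sums to its formal value.
    Atoms that already carry a type keep it (fixture bodies with custom types).

    A :class:`~synthgrid.crystal_structures.CrystalStructure` may be passed
    instead of a body: its expanded P1 cell is typed and charged in place and
    the structure itself is returned.
    """
    if hasattr(body, "expand_p1"):  # CrystalStructure, without a circular import
        structure = body
        exp = structure.expand_p1()
        proto = Body(exp.elements, exp.cart, charges=exp.charges, types=exp.types,
                     bonds=exp.bonds, units=exp.units, label="expanded cell")
        typed = assign_types_and_charges(proto, charge_scheme, charge_table, formal_charges)
        structure.with_charges_and_types(typed.charges, typed.types)
        return structure
    nbrs = body.neighbor_lists()
    types: list[str | None] = []
    roles: list[str] = []
    for i, el in enumerate(body.elements):
        t = body.types[i]
        if t is None:
            t = _dreiding_type(el, len(nbrs[i]))
        role = "none"
        if el == "H" and any(body.elements[j] in _HB_ELEMENTS for j in nbrs[i]):
            t = "H__HB" if t == "H_" else t
            role = "donor_h"
        elif el in _HB_ELEMENTS:
            role = "acceptor"
        types.append(t)
        roles.append(role)

    typed = Body(body.elements, body.xyz, body.charges, types, body.bonds,
                 body.units, body.label, roles)

    if charge_scheme == "gasteiger":
        q = gasteiger_charges(typed)
    elif charge_scheme == "table":
        if charge_table is None:
            raise ForceFieldError("charge_scheme='table' requires a charge_table")
        q = np.empty(len(typed))
        for i, el in enumerate(typed.elements):
            if el not in charge_table:
                raise ForceFieldError(f"charge table has no entry for label {el!r}")
            q[i] = charge_table[el]
    elif charge_scheme == "zero":
        q = np.zeros(len(typed))
    else:
        raise ForceFieldError(f"unknown charge scheme {charge_scheme!r}")

    if formal_charges is not None:
        if len(formal_charges) != len(typed.units):
            raise ForceFieldError(
                f"{len(formal_charges)} formal charges given for {len(typed.units)} molecular units"
            )
        for unit, target in zip(typed.units, formal_charges):
            shift = (target - q[unit].sum()) / len(unit)
            q[unit] += shift

    typed.charges = q
    return typed


# --------------------------------------------------------------------------
# energies


@dataclass(frozen=True)
class EnergyBreakdown:
    """Interaction energy decomposed into components (kcal/mol).

    ``polar`` is derived (electrostatic + hydrogen bond); ``total`` is the sum
    of the three stored components.
    """

    dispersive: float = 0.0
    electrostatic: float = 0.0
    hbond: float = 0.0

    @property
    def total(self) -> float:
        return self.dispersive + self.electrostatic + self.hbond

    @property
    def polar(self) -> float:
        return self.electrostatic + self.hbond

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.dispersive + other.dispersive,
            self.electrostatic + other.electrostatic,
            self.hbond + other.hbond,
        )

    def scaled(self, factor: float) -> "EnergyBreakdown":
        return EnergyBreakdown(self.dispersive * factor,
                               self.electrostatic * factor,
                               self.hbond * factor)

    def per_atom(self, natoms: int) -> "EnergyBreakdown":
        if natoms < 1:
            raise ValueError("atom count must be >= 1")
        return self.scaled(1.0 / natoms)


def _mix(params: FFParams, type_i: str, type_j: str) -> tuple[float, float]:
    d0i, r0i = params.lookup(type_i)
    d0j, r0j = params.lookup(type_j)
    d0 = math.sqrt(d0i * d0j)
    if params.r0_mixing == "arithmetic":
        r0 = 0.5 * (r0i + r0j)
    else:
        r0 = math.sqrt(r0i * r0j)
    return d0, r0


def _lj(d0: float, r0: float, r: float) -> float:
    s = r0 / r
    s2 = s * s
    s6 = s2 * s2 * s2
    return d0 * (s6 * s6 - 2.0 * s6)


def pair_energy(atom_i: Atom, atom_j: Atom, params: FFParams) -> EnergyBreakdown:
    """vdW + electrostatic energy of one atom pair (no hydrogen-bond geometry).

    The 12-10 hydrogen-bond term needs a D-H...A triple and is evaluated by
    :func:`hbond_energy` / :func:`body_body_energy`.
    """
    if atom_i.ff_type is None or atom_j.ff_type is None:
        raise ForceFieldError("both atoms must be typed")
    dx = atom_i.xyz[0] - atom_j.xyz[0]
    dy = atom_i.xyz[1] - atom_j.xyz[1]
    dz = atom_i.xyz[2] - atom_j.xyz[2]
    r = math.sqrt(dx * dx + dy * dy + dz * dz)
    if r == 0.0:
        raise ForceFieldError("atoms at zero separation")
    if r >= params.cutoff:
        return EnergyBreakdown()
    d0, r0 = _mix(params, atom_i.ff_type, atom_j.ff_type)
    disp = _lj(d0, r0, r)
    qi = atom_i.charge or 0.0
    qj = atom_j.charge or 0.0
    elec = params.coulomb_k * (qi * qj) / (params.dielectric * r)
    return EnergyBreakdown(dispersive=disp, electrostatic=elec)


def hbond_energy(donor_xyz, h_xyz, acceptor_xyz, params: FFParams) -> float:
    """Dreiding 12-10 hydrogen-bond energy for one D-H...A triple.

    Active only when the donor--acceptor distance is below the H-bond cutoff
    and the D-H...A angle exceeds 90 degrees; returns 0 otherwise.
    """
    d = np.asarray(donor_xyz, float)
    h = np.asarray(h_xyz, float)
    a = np.asarray(acceptor_xyz, float)
    rda_vec = a - d
    rda = math.sqrt(rda_vec[0] ** 2 + rda_vec[1] ** 2 + rda_vec[2] ** 2)
    if rda == 0.0:
        raise ForceFieldError("donor and acceptor at zero separation")
    if rda >= params.hb_cutoff:
        return 0.0
    u_hd = d - h
    u_ha = a - h
    nd = np.linalg.norm(u_hd)
    na = np.linalg.norm(u_ha)
    if nd == 0.0 or na == 0.0:
        return 0.0
    cos_theta = float(u_hd @ u_ha) / (nd * na)  # theta = D-H...A angle at H
    if cos_theta >= 0.0:  # angle <= 90 deg: no hydrogen bond
        return 0.0
    s = params.hb_r0 / rda
    s2 = s * s
    s10 = s2 * s2 * s2 * s2 * s2
    return params.hb_depth * (5.0 * s10 * s2 - 6.0 * s10) * cos_theta ** 4


def _hb_pairs(body_a: Body, body_b: Body, params: FFParams):
    """Active cross-body H-bond triples: list of (donor, h, acceptor, energy).

    Donor side may be on either body. Returns the per-triple energies and the
    set of (a_index, b_index) heavy-atom pairs whose LJ term is replaced.
    """
    energies: list[float] = []
    replaced: set[tuple[int, int]] = set()
    for (d, h) in body_a.donor_triples():
        for acc in body_b.acceptor_indices():
            e = hbond_energy(body_a.xyz[d], body_a.xyz[h], body_b.xyz[acc], params)
            if e != 0.0:
                energies.append(e)
                replaced.add((d, acc))
    for (d, h) in body_b.donor_triples():
        for acc in body_a.acceptor_indices():
            e = hbond_energy(body_b.xyz[d], body_b.xyz[h], body_a.xyz[acc], params)
            if e != 0.0:
                energies.append(e)
                replaced.add((acc, d))
    return energies, replaced


def body_body_energy(body_a: Body, body_b: Body, params: FFParams) -> EnergyBreakdown:
    """Total nonbonded interaction energy between two rigid bodies.

    Sums :func:`pair_energy` over all cross pairs within the cutoff plus the
    hydrogen-bond term over cross D-H...A triples; symmetric in its arguments.
    Component sums use ``math.fsum`` so the result does not depend on pair
    enumeration order.
    """
    body_a.require_typed()
    body_b.require_typed()

    diff = body_a.xyz[:, None, :] - body_b.xyz[None, :, :]
    r2 = diff[..., 0] ** 2 + diff[..., 1] ** 2 + diff[..., 2] ** 2
    if np.any(r2 == 0.0):
        i, j = np.argwhere(r2 == 0.0)[0]
        raise ForceFieldError(
            f"atoms {int(i)} of {body_a.label!r} and {int(j)} of {body_b.label!r} coincide"
        )
    r = np.sqrt(r2)
    within = r < params.cutoff

    hb_terms, replaced = _hb_pairs(body_a, body_b, params)
    if replaced:
        keep_lj = within.copy()
        for (ia, jb) in replaced:
            keep_lj[ia, jb] = False
    else:
        keep_lj = within

    # dispersive
    type_ids_a = [params.lookup(t) for t in body_a.types]  # raises if missing
    type_ids_b = [params.lookup(t) for t in body_b.types]
    d0a = np.array([p[0] for p in type_ids_a])
    r0a = np.array([p[1] for p in type_ids_a])
    d0b = np.array([p[0] for p in type_ids_b])
    r0b = np.array([p[1] for p in type_ids_b])
    d0 = np.sqrt(d0a[:, None] * d0b[None, :])
    if params.r0_mixing == "arithmetic":
        r0 = 0.5 * (r0a[:, None] + r0b[None, :])
    else:
        r0 = np.sqrt(r0a[:, None] * r0b[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(keep_lj, r0 / r, 0.0)
        s2 = s * s
        s6 = s2 * s2 * s2
        lj = d0 * (s6 * s6 - 2.0 * s6)
    dispersive = math.fsum(lj[keep_lj])

    # electrostatic
    qq = body_a.charges[:, None] * body_b.charges[None, :]
    elec_terms = params.coulomb_k * qq[within] / (params.dielectric * r[within])
    electrostatic = math.fsum(elec_terms)

    hbond = math.fsum(hb_terms)
    return EnergyBreakdown(dispersive=dispersive, electrostatic=electrostatic, hbond=hbond)
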