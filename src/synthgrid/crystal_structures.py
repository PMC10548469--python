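"""Crystal structures: CIF input, unit-cell mathematics, symmetry expansion.

A :class:`CrystalStructure` is the source of every body used downstream: the
asymmetric unit plus its symmetry operators generate the P1 cell content,
covalent-radius bond detection groups the expanded sites into molecular units
(molecules, counter-ions, hydrate waters), and supercell replication produces
finite :class:`~synthgrid.forcefield.Body` objects for energy work.

Cartesian convention (fixed for the whole package): lattice vector ``a`` lies
along +x, ``b`` in the xy-plane, right-handed frame.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .forcefield import Body
from .periodic import covalent_radius, is_known_element, normalize_element

__all__ = [
    "AtomSite",
    "CifFormatError",
    "CrystalStructure",
    "MillerIndex",
    "StructureError",
    "SymOp",
    "UnitCell",
    "build_supercell",
    "d_spacing",
    "frac_to_cart",
    "cart_to_frac",
    "parse_cif",
    "write_xyz",
]


class StructureError(ValueError):
    """Invalid crystal-structure content (overlaps, bad occupancies...)."""


class CifFormatError(StructureError):
    """Malformed or incomplete CIF input."""


# --------------------------------------------------------------------------
# unit cell


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise StructureError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise StructureError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise StructureError("cell metric is not positive definite")

    @property
    def matrix(self) -> np.ndarray:
        """Rows are the Cartesian lattice vectors a, b, c (a along +x, b in xy)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        cy = (ca - cb * cg) / sg
        czsq = 1.0 - cb * cb - cy * cy
        if czsq <= 0:
            raise StructureError("cell metric is not positive definite")
        return np.array([
            [self.a, 0.0, 0.0],
            [self.b * cg, self.b * sg, 0.0],
            [self.c * cb, self.c * cy, self.c * math.sqrt(czsq)],
        ])

    @property
    def volume(self) -> float:
        """Closed-form triclinic volume (Angstrom^3)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return float("nan")
        return self.a * self.b * self.c * math.sqrt(arg)


def frac_to_cart(cell: UnitCell | np.ndarray, frac) -> np.ndarray:
    """Fractional -> Cartesian (Angstrom) under the package convention."""
    m = cell.matrix if isinstance(cell, UnitCell) else np.asarray(cell, float)
    return np.asarray(frac, float) @ m


def cart_to_frac(cell: UnitCell | np.ndarray, cart) -> np.ndarray:
    m = cell.matrix if isinstance(cell, UnitCell) else np.asarray(cell, float)
    return np.asarray(cart, float) @ np.linalg.inv(m)


# --------------------------------------------------------------------------
# Miller indices


@dataclass(frozen=True)
class MillerIndex:
    """(h k l) in lowest integer terms, first nonzero component positive."""

    h: int
    k: int
    l: int

    def __post_init__(self) -> None:
        hkl = (self.h, self.k, self.l)
        if hkl == (0, 0, 0):
            raise StructureError("Miller index (0 0 0) is not a plane")
        g = math.gcd(math.gcd(abs(self.h), abs(self.k)), abs(self.l))
        red = tuple(x // g for x in hkl)
        first = next(x for x in red if x != 0)
        if first < 0:
            red = tuple(-x for x in red)
        object.__setattr__(self, "h", red[0])
        object.__setattr__(self, "k", red[1])
        object.__setattr__(self, "l", red[2])

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)

    def __str__(self) -> str:
        return f"({self.h} {self.k} {self.l})"


def d_spacing(cell: UnitCell | np.ndarray, hkl) -> float:
    """Interplanar spacing d_hkl = 1/|h a* + k b* + l c*| (Angstrom).

    ``hkl`` may be a :class:`MillerIndex` or a raw integer triple; raw triples
    are used as given (no gcd reduction), so d(n*hkl) = d(hkl)/n.
    """
    if isinstance(hkl, MillerIndex):
        hkl = hkl.as_tuple()
    h, k, l = hkl
    if (h, k, l) == (0, 0, 0):
        raise StructureError("d-spacing undefined for (0 0 0)")
    m = cell.matrix if isinstance(cell, UnitCell) else np.asarray(cell, float)
    recip = np.linalg.inv(m).T  # rows a*, b*, c* (no 2*pi)
    g = h * recip[0] + k * recip[1] + l * recip[2]
    return 1.0 / float(np.linalg.norm(g))


# --------------------------------------------------------------------------
# sites and symmetry


@dataclass
class AtomSite:
    """One asymmetric-unit site: element, label, fractional coordinates."""

    element: str
    label: str
    frac: np.ndarray
    charge: float | None = None
    ff_type: str | None = None

    def __post_init__(self) -> None:
        self.element = normalize_element(self.element)
        self.frac = np.asarray(self.frac, float).reshape(3)
        if not np.all(np.isfinite(self.frac)):
            raise StructureError(f"non-finite coordinates for site {self.label!r}")
        if not is_known_element(self.element):
            raise StructureError(f"unrecognized element {self.element!r} for site {self.label!r}")


@dataclass(frozen=True)
class SymOp:
    """Symmetry operator in fractional coordinates: x' = R x + t."""

    rot: tuple[tuple[int, int, int], ...]
    tran: tuple[float, float, float]

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymOp":
        import gemmi

        try:
            op = gemmi.Op(triplet)
        except Exception as exc:
            raise CifFormatError(f"unparseable symmetry operator {triplet!r}: {exc}") from exc
        rot = tuple(tuple(int(Fraction(v, op.DEN)) for v in row) for row in op.rot)
        tran = tuple(float(Fraction(v, op.DEN)) for v in op.tran)
        return cls(rot, tran)

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(self.rot, float) @ np.asarray(frac, float) + np.asarray(self.tran)

    def to_xyz(self) -> str:
        def term(row, t):
            parts = []
            for coef, var in zip(row, "xyz"):
                if coef == 1:
                    parts.append(f"+{var}")
                elif coef == -1:
                    parts.append(f"-{var}")
                elif coef != 0:
                    parts.append(f"{coef:+d}{var}")
            if t:
                parts.append(f"{Fraction(t).limit_denominator(24):+}")
            return "".join(parts).lstrip("+") or "0"

        return ",".join(term(r, t) for r, t in zip(self.rot, self.tran))


# --------------------------------------------------------------------------
# expanded cell representation

#: merge tolerance for duplicate symmetry images (Angstrom)
MERGE_TOL = 1e-3
#: hard clash tolerance between distinct expanded sites (Angstrom)
CLASH_TOL = 0.5
#: covalent-radius scale factor for bond detection
BOND_SCALE = 1.15


@dataclass
class ExpandedCell:
    """P1 content of one unit cell with whole-molecule bookkeeping.

    ``frac`` rows are unwrapped fractional coordinates: every molecular unit
    is contiguous in space (atoms of a molecule straddling the cell boundary
    keep their bonded geometry) while each unit's first atom lies in [0, 1).
    """

    matrix: np.ndarray                     # Cartesian lattice vectors (rows)
    elements: list[str]
    frac: np.ndarray
    parents: list[int]                     # asymmetric-unit site index per atom
    bonds: list[tuple[int, int]]           # intra-cell, after unwrapping
    units: list[list[int]]
    charges: np.ndarray | None = None
    types: list[str | None] | None = None

    @property
    def cart(self) -> np.ndarray:
        return self.frac @ self.matrix

    @property
    def natoms(self) -> int:
        return len(self.elements)


class CrystalStructure:
    """Unit cell + asymmetric unit + symmetry operators.

    ``matrix`` may override the conventional Cartesian basis (used by
    surface-aligned descriptions where +z is the surface normal); it must
    describe the same lattice metric as ``cell``.
    """

    def __init__(
        self,
        cell: UnitCell,
        sites: Sequence[AtomSite],
        ops: Sequence[SymOp] | None = None,
        spacegroup: str = "P 1",
        matrix: np.ndarray | None = None,
        bond_scale: float = BOND_SCALE,
    ) -> None:
        if not sites:
            raise StructureError("a crystal structure needs at least one atom site")
        self.cell = cell
        self.sites = list(sites)
        self.ops = list(ops) if ops else [SymOp.identity()]
        self.spacegroup = spacegroup
        self.matrix = cell.matrix if matrix is None else np.asarray(matrix, float)
        self.bond_scale = bond_scale
        self._expanded: ExpandedCell | None = None

    # -- symmetry expansion ------------------------------------------------

    def expand_p1(self) -> ExpandedCell:
        """Apply all operators, fold to [0,1), merge duplicates, find units."""
        if self._expanded is not None:
            return self._expanded
        m = self.matrix
        elements: list[str] = []
        frac_list: list[np.ndarray] = []
        parents: list[int] = []
        for op in self.ops:
            for idx, site in enumerate(self.sites):
                f = op.apply(site.frac) % 1.0
                cart = f @ m
                dup = False
                for g in frac_list:
                    delta = (f - g + 0.5) % 1.0 - 0.5
                    if np.linalg.norm(delta @ m) < MERGE_TOL:
                        dup = True
                        break
                if not dup:
                    elements.append(site.element)
                    frac_list.append(f)
                    parents.append(idx)
        frac = np.array(frac_list)
        self._check_clashes(frac, m, elements)
        bonds, shifts = self._detect_bonds(elements, frac, m)
        units, frac = self._unwrap_units(frac, bonds, shifts)
        charges = None
        if all(self.sites[p].charge is not None for p in parents):
            charges = np.array([self.sites[p].charge for p in parents], float)
        types = [self.sites[p].ff_type for p in parents]
        if all(t is None for t in types):
            types = None
        self._expanded = ExpandedCell(m, elements, frac, parents, bonds, units,
                                      charges, types)
        return self._expanded

    @staticmethod
    def _check_clashes(frac: np.ndarray, m: np.ndarray, elements: list[str]) -> None:
        n = len(frac)
        for i in range(n):
            delta = (frac[i + 1:] - frac[i] + 0.5) % 1.0 - 0.5
            if len(delta) == 0:
                continue
            d = np.linalg.norm(delta @ m, axis=1)
            j = np.argmin(d) if len(d) else 0
            if len(d) and d[j] < CLASH_TOL:
                raise StructureError(
                    f"symmetry-expanded sites {i} and {i + 1 + int(j)} overlap "
                    f"({d[j]:.3f} A apart, elements {elements[i]}/{elements[i + 1 + int(j)]})"
                )

    def _detect_bonds(self, elements, frac, m):
        """Minimum-image covalent bonds; returns bonds and their image shifts."""
        bonds: list[tuple[int, int]] = []
        shifts: dict[tuple[int, int], np.ndarray] = {}
        if self.bond_scale <= 0:
            return bonds, shifts
        radii = np.array([covalent_radius(e) for e in elements])
        n = len(elements)
        images = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
        for i in range(n):
            for j in range(i + 1, n):
                dmin, best = None, None
                for img in images:
                    d = np.linalg.norm((frac[j] + img - frac[i]) @ m)
                    if dmin is None or d < dmin:
                        dmin, best = d, img
                if dmin is not None and dmin < self.bond_scale * (radii[i] + radii[j]):
                    bonds.append((i, j))
                    shifts[(i, j)] = best
        return bonds, shifts

    @staticmethod
    def _unwrap_units(frac, bonds, shifts):
        """Connected components of the bond graph, unwrapped to be whole."""
        n = len(frac)
        adj: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(n)]
        for (i, j) in bonds:
            s = shifts[(i, j)]
            adj[i].append((j, s))
            adj[j].append((i, -s))
        seen = [False] * n
        offset = np.zeros((n, 3))
        units: list[list[int]] = []
        for start in range(n):
            if seen[start]:
                continue
            comp = [start]
            seen[start] = True
            queue = [start]
            while queue:
                i = queue.pop()
                for (j, s) in adj[i]:
                    cand = offset[i] + s
                    if not seen[j]:
                        seen[j] = True
                        offset[j] = cand
                        comp.append(j)
                        queue.append(j)
                    elif not np.allclose(offset[j], cand):
                        raise StructureError(
                            "covalent network wraps around the cell; "
                            "molecular units cannot be made whole"
                        )
            units.append(sorted(comp))
        return units, frac + offset

    # -- derived descriptions ----------------------------------------------

    def molecular_unit_count(self) -> int:
        return len(self.expand_p1().units)

    def with_charges_and_types(self, charges, types) -> None:
        """Write per-expanded-atom charges/types back onto the expanded cell."""
        exp = self.expand_p1()
        exp.charges = np.asarray(charges, float)
        exp.types = list(types)

    def write_cif(self, path) -> None:
        """Write the expanded cell as a P1 CIF."""
        exp = self.expand_p1()
        c = self.cell
        lines = [
            "data_synthgrid",
            f"_cell_length_a {c.a:.6f}",
            f"_cell_length_b {c.b:.6f}",
            f"_cell_length_c {c.c:.6f}",
            f"_cell_angle_alpha {c.alpha:.6f}",
            f"_cell_angle_beta {c.beta:.6f}",
            f"_cell_angle_gamma {c.gamma:.6f}",
            "_symmetry_space_group_name_H-M 'P 1'",
            "loop_",
            "_symmetry_equiv_pos_as_xyz",
            "x,y,z",
            "loop_",
            "_atom_site_label",
            "_atom_site_type_symbol",
            "_atom_site_fract_x",
            "_atom_site_fract_y",
            "_atom_site_fract_z",
        ]
        for i, (el, f) in enumerate(zip(exp.elements, exp.frac % 1.0)):
            lines.append(f"{el}{i + 1} {el} {f[0]:.6f} {f[1]:.6f} {f[2]:.6f}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# supercell


def build_supercell(structure: CrystalStructure, na: int, nb: int, nc: int,
                    label: str | None = None) -> Body:
    """Replicate the expanded P1 cell na x nb x nc into a finite Body."""
    if min(na, nb, nc) < 1:
        raise StructureError("supercell repeats must be >= 1")
    exp = structure.expand_p1()
    m = exp.matrix
    elements: list[str] = []
    xyz: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    units: list[list[int]] = []
    charges: list[float] = []
    types: list[str | None] = []
    base = 0
    for i in range(na):
        for j in range(nb):
            for k in range(nc):
                shift = np.array([i, j, k], float)
                elements.extend(exp.elements)
                xyz.append((exp.frac + shift) @ m)
                bonds.extend((a + base, b + base) for a, b in exp.bonds)
                units.extend([idx + base for idx in u] for u in exp.units)
                if exp.charges is not None:
                    charges.extend(exp.charges)
                if exp.types is not None:
                    types.extend(exp.types)
                base += exp.natoms
    return Body(
        elements,
        np.vstack(xyz),
        charges=np.array(charges) if charges else None,
        types=types if types else None,
        bonds=bonds,
        units=units,
        label=label or f"{structure.spacegroup} {na}x{nb}x{nc} supercell",
    )


# --------------------------------------------------------------------------
# CIF input


_ESD = re.compile(r"\(\d+\)\s*$")


def _cif_number(raw: str, tag: str) -> float:
    if raw is None:
        raise CifFormatError(f"missing CIF tag {tag}")
    val = _ESD.sub("", raw.strip())
    try:
        return float(val)
    except ValueError:
        raise CifFormatError(f"cannot parse {tag} value {raw!r}") from None


def parse_cif(path) -> CrystalStructure:
    """Read a core-dictionary CIF (first data block) into a CrystalStructure.

    Charges are left unset; molecular units are found by covalent-radius bond
    detection on the expanded cell. Sites with partial occupancy are rejected.
    """
    import gemmi

    try:
        doc = gemmi.cif.read_file(str(path))
    except Exception as exc:
        raise CifFormatError(f"cannot read CIF {path}: {exc}") from exc
    if len(doc) == 0:
        raise CifFormatError(f"no data block in {path}")
    block = doc[0]

    cell_vals = {}
    for tag in ("_cell_length_a", "_cell_length_b", "_cell_length_c",
                "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma"):
        cell_vals[tag] = _cif_number(block.find_value(tag), tag)
    cell = UnitCell(
        cell_vals["_cell_length_a"], cell_vals["_cell_length_b"], cell_vals["_cell_length_c"],
        cell_vals["_cell_angle_alpha"], cell_vals["_cell_angle_beta"], cell_vals["_cell_angle_gamma"],
    )

    ops: list[SymOp] = []
    for tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        if len(col) > 0:
            ops = [SymOp.from_xyz(gemmi.cif.as_string(v)) for v in col]
            break
    if not ops:
        ops = [SymOp.identity()]

    sg = "P 1"
    for tag in ("_symmetry_space_group_name_H-M", "_space_group_name_H-M_alt"):
        v = block.find_value(tag)
        if v:
            sg = gemmi.cif.as_string(v)
            break

    table = block.find("_atom_site_", ["label", "fract_x", "fract_y", "fract_z"])
    if len(table) == 0:
        raise CifFormatError(f"no atom sites in {path}")
    sym_col = block.find_loop("_atom_site_type_symbol")
    occ_col = block.find_loop("_atom_site_occupancy")
    sites: list[AtomSite] = []
    for i, row in enumerate(table):
        label = gemmi.cif.as_string(row[0])
        if len(occ_col) > 0:
            occ = _cif_number(gemmi.cif.as_string(occ_col[i]), "_atom_site_occupancy")
            if occ < 1.0:
                raise StructureError(
                    f"site {label!r} has partial occupancy {occ}; disorder is not supported"
                )
        symbol = gemmi.cif.as_string(sym_col[i]) if len(sym_col) > 0 else label
        frac = [_cif_number(gemmi.cif.as_string(row[j]), f"_atom_site_fract_{ax}")
                for j, ax in ((1, "x"), (2, "y"), (3, "z"))]
        sites.append(AtomSite(normalize_element(symbol), label, np.array(frac) % 1.0))

    return CrystalStructure(cell, sites, ops, spacegroup=sg)


def write_xyz(body: Body, path, comment: str = "") -> None:
    """Write a Body as plain XYZ (element + Cartesian Angstrom)."""
    with open(path, "w") as fh:
        fh.write(f"{len(body)}\n{comment or body.label}\n")
        for el, (x, y, z) in zip(body.elements, body.xyz):
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
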