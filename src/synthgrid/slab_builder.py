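"""Crystal surface slabs: alignment, terminations, attachment energy, BFDH.

The route from bulk crystal to a surface body is:

1. :func:`surface_aligned_cell` re-describes the lattice by an integer
   (unimodular) recombination of cell vectors so that two vectors span the
   (hkl) plane and the plane normal points along +z;
2. :func:`scan_terminations` cuts the stacking at ten candidate offsets
   (0.1 d_hkl apart through one d-spacing), computing for each the slice
   energy E_slice (interactions inside one growth layer) and the attachment
   energy E_att = E_latt - E_slice; the most stable termination minimizes
   |E_att|;
3. :func:`build_slab` materializes a finite slab body at the chosen cut,
   keeping molecular units whole (membership decided by centroid height);
4. :func:`rugosity` quantifies how corrugated the exposed face is.

Energies are reported per asymmetric unit in kcal/mol. All lattice sums are
direct (no Ewald); electrostatically charged lattices should be summed over
charge-neutral groups of whole cells (``cell_shells``) to tame conditional
convergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .crystal_structures import (
    CrystalStructure,
    ExpandedCell,
    MillerIndex,
    StructureError,
    UnitCell,
    d_spacing,
)
from .forcefield import Body, EnergyBreakdown, FFParams, body_body_energy
from .periodic import vdw_radius

__all__ = [
    "BFDHFace",
    "LatticeSum",
    "Slab",
    "Termination",
    "TerminationScan",
    "attachment_energy",
    "bfdh_faces",
    "build_slab",
    "lattice_energy",
    "rugosity",
    "scan_terminations",
    "surface_aligned_cell",
]


# --------------------------------------------------------------------------
# surface-aligned lattice description


def _xgcd(a: int, b: int) -> tuple[int, int, int]:
    """g, x, y with a*x + b*y = g = gcd(a, b)."""
    old_r, r = a, b
    old_s, s = 1, 0
    old_t, t = 0, 1
    while r:
        qq = old_r // r
        old_r, r = r, old_r - qq * r
        old_s, s = s, old_s - qq * s
        old_t, t = t, old_t - qq * t
    if old_r < 0:
        old_r, old_s, old_t = -old_r, -old_s, -old_t
    return old_r, old_s, old_t


def _plane_basis(hkl: MillerIndex) -> np.ndarray:
    """Unimodular integer matrix with rows (v1, v2, t): v1,v2 in the (hkl)
    plane, t a stacking vector with h*t1 + k*t2 + l*t3 = 1."""
    h, k, l = hkl.as_tuple()
    if k == 0 and l == 0:   # reduced => h == 1
        m = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
    elif h == 0 and l == 0:  # k == 1
        m = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]])
    elif h == 0 and k == 0:  # l == 1
        m = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
    else:
        g, p, q = _xgcd(k, l)
        v1 = (0, l // g, -k // g)
        v2 = (g, -p * h, -q * h)
        g2, u, v = _xgcd(h, g)  # g2 == 1 for a reduced index
        t = (u, v * p, v * q)
        m = np.array([v1, v2, t])
    det = round(np.linalg.det(m))
    if det == -1:
        m[[0, 1]] = m[[1, 0]]
        det = 1
    if det != 1:
        raise StructureError(f"no unimodular plane basis found for {hkl}")
    return m


def surface_aligned_cell(structure: CrystalStructure, hkl) -> CrystalStructure:
    """Equivalent P1 lattice description with the (hkl) normal along +z.

    The returned structure has an explicit Cartesian basis whose first two
    vectors lie in the z = 0 plane (both exactly perpendicular to the
    normal) and whose third vector advances one d-spacing along +z per cell.
    Cell volume and atom content are preserved exactly.
    """
    hkl = hkl if isinstance(hkl, MillerIndex) else MillerIndex(*hkl)
    m_int = _plane_basis(hkl)
    a_old = structure.matrix
    vecs = m_int @ a_old  # rows: V1, V2, T in the old Cartesian frame

    recip = np.linalg.inv(a_old).T
    g = hkl.h * recip[0] + hkl.k * recip[1] + hkl.l * recip[2]
    d = 1.0 / np.linalg.norm(g)
    e3 = g * d
    e1 = vecs[0] / np.linalg.norm(vecs[0])
    e2 = np.cross(e3, e1)
    rot = np.vstack([e1, e2, e3])
    new_matrix = vecs @ rot.T
    # in-plane vectors have exactly zero z-component by construction
    new_matrix[0, 1:] = 0.0
    new_matrix[1, 2] = 0.0

    exp = structure.expand_p1()
    inv_m = np.linalg.inv(m_int)
    new_frac = (exp.frac @ inv_m) % 1.0

    lengths = np.linalg.norm(new_matrix, axis=1)
    def ang(u, v):
        return math.degrees(math.acos(float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))))
    cell = UnitCell(lengths[0], lengths[1], lengths[2],
                    ang(new_matrix[1], new_matrix[2]),
                    ang(new_matrix[0], new_matrix[2]),
                    ang(new_matrix[0], new_matrix[1]))

    from .crystal_structures import AtomSite
    sites = [
        AtomSite(el, f"{el}{i + 1}", f,
                 charge=None if exp.charges is None else float(exp.charges[i]),
                 ff_type=None if exp.types is None else exp.types[i])
        for i, (el, f) in enumerate(zip(exp.elements, new_frac))
    ]
    aligned = CrystalStructure(cell, sites, spacegroup="P 1", matrix=new_matrix,
                               bond_scale=structure.bond_scale)
    aligned.aligned_hkl = hkl
    aligned.layer_spacing = float(new_matrix[2, 2])
    if hasattr(structure, "toy_types"):
        aligned.toy_types = structure.toy_types
    return aligned


# --------------------------------------------------------------------------
# lattice sums


@dataclass(frozen=True)
class LatticeSum:
    """Lattice energy per asymmetric unit with convergence diagnostics."""

    energy: EnergyBreakdown
    converged: bool
    delta: float                 # change of total over the last shell (kcal/mol)
    neutral: bool                # cell charge neutrality

    @property
    def total(self) -> float:
        return self.energy.total


def _unit_centroids(exp: ExpandedCell) -> np.ndarray:
    cart = exp.cart
    return np.array([cart[u].mean(axis=0) for u in exp.units])


def _unit_body(exp: ExpandedCell, selection: list[tuple[np.ndarray, int]],
               label: str) -> Body | None:
    """Concatenate image copies of units into one Body (bonds/roles kept)."""
    if not selection:
        return None
    elements: list[str] = []
    xyz: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    charges: list[float] = []
    types: list[str | None] = []
    units: list[list[int]] = []
    m = exp.matrix
    base = 0
    unit_bonds = [
        [(i, j) for (i, j) in exp.bonds if i in set(u) and j in set(u)]
        for u in exp.units
    ]
    for shift, ui in selection:
        u = exp.units[ui]
        remap = {a: base + n for n, a in enumerate(u)}
        elements.extend(exp.elements[a] for a in u)
        xyz.append((exp.frac[u] + shift) @ m)
        bonds.extend((remap[i], remap[j]) for (i, j) in unit_bonds[ui])
        if exp.charges is not None:
            charges.extend(exp.charges[a] for a in u)
        if exp.types is not None:
            types.extend(exp.types[a] for a in u)
        units.append([base + n for n in range(len(u))])
        base += len(u)
    body = Body(elements, np.vstack(xyz),
                charges=np.array(charges) if charges else None,
                types=types if types else None,
                bonds=bonds, units=units, label=label)
    return body


def _typed_roles(body: Body) -> Body:
    """Infer donor/acceptor roles from elements + bonds without retyping."""
    from .forcefield import _HB_ELEMENTS
    nbrs = body.neighbor_lists()
    roles = []
    for i, el in enumerate(body.elements):
        if el == "H" and any(body.elements[j] in _HB_ELEMENTS for j in nbrs[i]):
            roles.append("donor_h")
        elif el in _HB_ELEMENTS:
            roles.append("acceptor")
        else:
            roles.append("none")
    body.hb_roles = roles
    return body


def _neighbor_shifts(exp: ExpandedCell, reach: float) -> list[np.ndarray]:
    """All integer cell shifts whose cell could hold a unit within ``reach``."""
    m = exp.matrix
    vol = abs(np.linalg.det(m))
    perp = [vol / np.linalg.norm(np.cross(m[(i + 1) % 3], m[(i + 2) % 3])) for i in range(3)]
    nmax = [int(math.ceil(reach / p)) + 1 for p in perp]
    return [np.array([i, j, k], float)
            for i in range(-nmax[0], nmax[0] + 1)
            for j in range(-nmax[1], nmax[1] + 1)
            for k in range(-nmax[2], nmax[2] + 1)]


def _selected_images(exp: ExpandedCell, radius: float | None,
                     cell_shells: int | None):
    """(shift, unit) pairs around the home cell, per central unit.

    Returns a function mapping a central-unit centroid to the selection, so
    radius-based selection is centered on each unit in turn.
    """
    centroids = _unit_centroids(exp)
    if cell_shells is not None:
        shifts = [np.array([i, j, k], float)
                  for i in range(-cell_shells, cell_shells + 1)
                  for j in range(-cell_shells, cell_shells + 1)
                  for k in range(-cell_shells, cell_shells + 1)]

        def select(center, skip):
            out = []
            for s in shifts:
                home = np.all(s == 0)
                for ui in range(len(exp.units)):
                    if home and ui == skip:
                        continue
                    out.append((s, ui))
            return out

        return select

    assert radius is not None
    diam = 0.0
    cart = exp.cart
    for u in exp.units:
        if len(u) > 1:
            diam = max(diam, np.ptp(cart[u], axis=0).max())
    shifts = _neighbor_shifts(exp, radius + diam)
    m = exp.matrix

    def select(center, skip):
        out = []
        for s in shifts:
            home = np.all(s == 0)
            offs = centroids + s @ m
            dist = np.linalg.norm(offs - center, axis=1)
            for ui in range(len(exp.units)):
                if home and ui == skip:
                    continue
                if dist[ui] <= radius:
                    out.append((s, ui))
        return out

    return select


def _half_sum(structure: CrystalStructure, params: FFParams,
              radius: float | None, cell_shells: int | None,
              classify=None) -> dict[str, EnergyBreakdown]:
    """Half-sum of central-unit interactions, optionally split into groups.

    ``classify(central_unit_index, central_layer, shift, unit_index) -> key``
    routes each neighbor's contribution; default is a single "all" group.
    Result is per asymmetric unit (divided by the operator count of the
    original setting, i.e. by units-per-cell over units-per-asymmetric-unit).
    """
    exp = structure.expand_p1()
    if exp.types is None or exp.charges is None:
        raise StructureError("structure must carry atom types and charges; "
                             "run assign_types_and_charges first")
    centroids = _unit_centroids(exp)
    select = _selected_images(exp, radius, cell_shells)
    groups: dict[str, EnergyBreakdown] = {}
    for cu in range(len(exp.units)):
        central = _typed_roles(_unit_body(exp, [(np.zeros(3), cu)], "central"))
        buckets: dict[str, list[tuple[np.ndarray, int]]] = {}
        for (s, ui) in select(centroids[cu], cu):
            key = "all" if classify is None else classify(cu, s, ui)
            buckets.setdefault(key, []).append((s, ui))
        for key, sel in buckets.items():
            nb = _typed_roles(_unit_body(exp, sel, "environment"))
            e = body_body_energy(central, nb, params)
            groups[key] = groups.get(key, EnergyBreakdown()) + e
    # per asymmetric unit: the P1 expansion holds one copy per operator
    n_asym_copies = max(1, len(structure.ops))
    return {k: v.scaled(0.5 / n_asym_copies) for k, v in groups.items()}


def lattice_energy(structure: CrystalStructure, params: FFParams,
                   radius: float | None = 25.0,
                   cell_shells: int | None = None) -> LatticeSum:
    """Lattice energy per asymmetric unit by direct summation.

    ``radius`` selects whole molecular units whose centroid lies within the
    given distance of the central unit's centroid; ``cell_shells`` instead
    sums over complete (charge-neutral) unit cells within an n-shell cube,
    which is the right truncation for ionic lattices. Exactly one of the two
    must be given. Pair-level truncation inside the sum follows
    ``params.cutoff``; pass an infinite cutoff to make group selection the
    only truncation.
    """
    if (radius is None) == (cell_shells is None):
        raise ValueError("give exactly one of radius or cell_shells")
    exp = structure.expand_p1()
    neutral = exp.charges is None or abs(float(np.sum(exp.charges))) < 1e-8

    e_full = _half_sum(structure, params, radius, cell_shells).get("all", EnergyBreakdown())
    # convergence probe: shrink the summation region by one cell
    if cell_shells is not None:
        probe = max(cell_shells - 1, 0) or None
        e_small = (_half_sum(structure, params, None, probe).get("all", EnergyBreakdown())
                   if probe else EnergyBreakdown())
    else:
        shrink = max(radius - np.linalg.norm(exp.matrix, axis=1).max(), 0.0)
        e_small = (_half_sum(structure, params, shrink, None).get("all", EnergyBreakdown())
                   if shrink > 0 else EnergyBreakdown())
    delta = abs(e_full.total - e_small.total)
    tol = max(1e-6, 1e-3 * abs(e_full.total))
    return LatticeSum(e_full, converged=delta < tol, delta=delta, neutral=neutral)


# --------------------------------------------------------------------------
# terminations and attachment energy


@dataclass(frozen=True)
class Termination:
    """One candidate surface cut: offset in units of d_hkl, energies per
    asymmetric unit (kcal/mol). E_latt = E_slice + E_att by construction;
    the stored ``e_latt`` is summed independently over the full environment
    so the identity is a real check, not a tautology."""

    miller: MillerIndex
    offset: float
    e_slice: float
    e_att: float
    e_latt: float

    @property
    def partition_error(self) -> float:
        return abs(self.e_latt - (self.e_slice + self.e_att))


@dataclass(frozen=True)
class TerminationScan:
    terminations: tuple[Termination, ...]
    selected_index: int

    @property
    def selected(self) -> Termination:
        return self.terminations[self.selected_index]


def attachment_energy(structure: CrystalStructure, hkl, offset: float,
                      params: FFParams, radius: float = 25.0) -> Termination:
    """Slice/attachment energy partition for one termination offset.

    The structure must be surface-aligned (or alignable: a plain structure is
    aligned on the fly). Growth layers are slabs of thickness d_hkl with
    boundaries at z = (offset + m) d; a molecular unit belongs to the layer
    containing its centroid. E_slice counts neighbors in the central unit's
    own layer, E_att neighbors in all other layers.
    """
    hkl = hkl if isinstance(hkl, MillerIndex) else MillerIndex(*hkl)
    aligned = structure
    if getattr(structure, "aligned_hkl", None) != hkl:
        aligned = surface_aligned_cell(structure, hkl)
    d = aligned.layer_spacing
    exp = aligned.expand_p1()
    centroids = _unit_centroids(exp)

    def layer_of(z: float) -> int:
        # epsilon guards against float cancellation when a centroid sits
        # exactly on a layer boundary: such units join the layer above,
        # and all periodic images are classified consistently
        return math.floor(z / d - offset + 1e-9)

    def classify(cu, shift, ui):
        zc = centroids[cu][2]
        zn = centroids[ui][2] + shift[2] * d
        return "slice" if layer_of(zn) == layer_of(zc) else "att"

    groups = _half_sum(aligned, params, radius, None, classify=classify)
    e_slice = groups.get("slice", EnergyBreakdown()).total
    e_att = groups.get("att", EnergyBreakdown()).total
    e_latt = _half_sum(aligned, params, radius, None).get("all", EnergyBreakdown()).total
    return Termination(hkl, float(offset), e_slice, e_att, e_latt)


def scan_terminations(structure: CrystalStructure, hkl, params: FFParams,
                      step: float = 0.1, radius: float = 25.0) -> TerminationScan:
    """Enumerate terminations every ``step`` d-spacings through one d_hkl.

    ``step`` must divide 1 into an integer number of offsets (default 0.1,
    ten candidates). The selected termination minimizes |E_att|; ties go to
    the smallest offset.
    """
    n = round(1.0 / step)
    if n < 1 or abs(n * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide one d-spacing evenly")
    hkl = hkl if isinstance(hkl, MillerIndex) else MillerIndex(*hkl)
    aligned = surface_aligned_cell(structure, hkl)
    terms = tuple(attachment_energy(aligned, hkl, i * step, params, radius)
                  for i in range(n))
    best = min(abs(t.e_att) for t in terms)
    selected = next(i for i, t in enumerate(terms) if abs(t.e_att) <= best + 1e-9)
    return TerminationScan(terms, selected)


# --------------------------------------------------------------------------
# BFDH morphology


@dataclass(frozen=True)
class BFDHFace:
    miller: MillerIndex
    d_eff: float                 # d-spacing after extinction doubling (Angstrom)
    family: tuple[MillerIndex, ...]


def _is_extinct(hkl: tuple[int, int, int], ops) -> bool:
    h = np.array(hkl)
    for op in ops:
        rot = np.array(op.rot)
        if np.array_equal(h @ rot, h):
            phase = float(h @ np.array(op.tran))
            if abs(phase - round(phase)) > 1e-9:
                return True
    return False


def bfdh_faces(structure: CrystalStructure, n: int = 5, bound: int = 3) -> list[BFDHFace]:
    """Rank low-index faces by interplanar spacing (BFDH morphology rule).

    Faces whose reflection is systematically absent for the stored operators
    are assigned the d-spacing of the first allowed multiple (e.g. an absent
    (010) is scored as (020)), which is the standard BFDH demotion of screw
    and glide related faces. Symmetry-equivalent faces are grouped and one
    representative per family returned, most morphologically important (largest
    effective d) first.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seen: set[tuple[int, int, int]] = set()
    faces: list[tuple[tuple[int, int, int], float]] = []
    for h in range(-bound, bound + 1):
        for k in range(-bound, bound + 1):
            for l in range(-bound, bound + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                mi = MillerIndex(h, k, l)
                t = mi.as_tuple()
                if t in seen:
                    continue
                seen.add(t)
                mult = 1
                while mult <= 4 and _is_extinct(tuple(mult * x for x in t), structure.ops):
                    mult += 1
                d_eff = d_spacing(structure.cell, tuple(mult * x for x in t))
                faces.append((t, d_eff))

    # group symmetry-equivalent faces under the rotational parts (+ Friedel)
    rots = [np.array(op.rot) for op in structure.ops]
    family_of: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    families: dict[tuple[int, int, int], list[tuple[int, int, int]]] = {}
    for (t, _) in faces:
        if t in family_of:
            continue
        members = set()
        h = np.array(t)
        for rot in rots:
            for sign in (1, -1):
                img = tuple(int(x) for x in sign * (h @ rot))
                try:
                    members.add(MillerIndex(*img).as_tuple())
                except StructureError:
                    pass
        members.add(t)
        rep = max(members)
        for mm in members:
            family_of[mm] = rep
        families[rep] = sorted(members, reverse=True)

    ranked: dict[tuple[int, int, int], float] = {}
    for (t, d_eff) in faces:
        rep = family_of[t]
        ranked[rep] = max(ranked.get(rep, 0.0), d_eff)
    order = sorted(ranked.items(),
                   key=lambda kv: (-kv[1], tuple(-abs(x) for x in kv[0]),
                                   tuple(-x for x in kv[0])))
    out = []
    for rep, d_eff in order[:n]:
        fam = tuple(MillerIndex(*mm) for mm in families[rep])
        out.append(BFDHFace(MillerIndex(*rep), d_eff, fam))
    return out


# --------------------------------------------------------------------------
# slabs


@dataclass
class Slab:
    """A finite surface slab with its normal along +z."""

    body: Body
    miller: MillerIndex
    termination: Termination
    repeats: tuple[int, int]
    layers: int
    area: float                  # exposed-face area (Angstrom^2)
    d_hkl: float
    top_z: float                 # z of the cut plane

    @property
    def natoms(self) -> int:
        return len(self.body)


def build_slab(structure: CrystalStructure, hkl, termination: Termination,
               in_plane_repeats: tuple[int, int] = (3, 3),
               layers: int = 1) -> Slab:
    """Cut a finite slab at the given termination.

    Keeps every molecular unit whole: a unit belongs to the slab when its
    centroid lies within ``layers`` d-spacings below the cut plane. A
    one-layer slab is the "first molecular layer" probe surface.
    """
    if layers < 1 or min(in_plane_repeats) < 1:
        raise StructureError("layers and in-plane repeats must be >= 1")
    hkl = hkl if isinstance(hkl, MillerIndex) else MillerIndex(*hkl)
    aligned = structure
    if getattr(structure, "aligned_hkl", None) != hkl:
        aligned = surface_aligned_cell(structure, hkl)
    d = aligned.layer_spacing
    exp = aligned.expand_p1()
    centroids = _unit_centroids(exp)
    z_cut = termination.offset * d
    z_bottom = z_cut - layers * d

    na, nb = in_plane_repeats
    kmin = math.floor((z_bottom - centroids[:, 2].max()) / d) - 1
    kmax = math.ceil((z_cut - centroids[:, 2].min()) / d) + 1

    selection: list[tuple[np.ndarray, int]] = []
    for i in range(na):
        for j in range(nb):
            for k in range(kmin, kmax + 1):
                shift = np.array([i, j, k], float)
                for ui in range(len(exp.units)):
                    zc = centroids[ui][2] + k * d
                    if z_bottom <= zc < z_cut:
                        selection.append((shift, ui))
    if not selection:
        raise StructureError("no molecular units fall inside the requested slab")
    body = _typed_roles(_unit_body(exp, selection, f"slab {hkl} x{na}x{nb} L{layers}"))
    m = exp.matrix
    area = float(np.linalg.norm(np.cross(m[0], m[1]))) * na * nb
    return Slab(body, hkl, termination, (na, nb), layers, area, d, z_cut)


def rugosity(slab: Slab, grid_resolution: float = 0.2) -> float:
    """True-over-projected area ratio of the exposed face (>= 1).

    A height map is sampled on an in-plane grid: at each point the height is
    the top of the highest covering atomic van der Waals sphere. The mapped
    surface is triangulated (two triangles per grid cell) and its area is
    divided by the projected footprint area. Grid points not covered by any
    sphere take the lowest covered height, so isolated spheres read as bumps
    on a plane.
    """
    if grid_resolution <= 0:
        raise ValueError("grid resolution must be positive")
    xyz = slab.body.xyz
    radii = slab.body.vdw_radii()
    xmin, ymin = xyz[:, 0].min(), xyz[:, 1].min()
    xmax, ymax = xyz[:, 0].max(), xyz[:, 1].max()
    if xmax - xmin < grid_resolution or ymax - ymin < grid_resolution:
        return 1.0
    xs = np.arange(xmin, xmax + grid_resolution / 2, grid_resolution)
    ys = np.arange(ymin, ymax + grid_resolution / 2, grid_resolution)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    h = np.full(gx.shape, -np.inf)
    for (x, y, z), r in zip(xyz, radii):
        dx = gx - x
        dy = gy - y
        mask = dx * dx + dy * dy < r * r
        cap = z + np.sqrt(np.maximum(r * r - dx * dx - dy * dy, 0.0))
        h = np.where(mask, np.maximum(h, cap), h)
    covered = np.isfinite(h)
    if not covered.any():
        return 1.0
    h[~covered] = h[covered].min()

    dx = np.diff(xs)
    dy = np.diff(ys)
    area = 0.0
    # two triangles per cell: (i,j)-(i+1,j)-(i,j+1) and (i+1,j)-(i+1,j+1)-(i,j+1)
    for tri in (((0, 0), (1, 0), (0, 1)), ((1, 0), (1, 1), (0, 1))):
        p = [np.stack([gx[_sl(a, b, gx.shape)], gy[_sl(a, b, gx.shape)],
                       h[_sl(a, b, gx.shape)]], axis=-1) for (a, b) in tri]
        cross = np.cross(p[1] - p[0], p[2] - p[0])
        area += 0.5 * np.linalg.norm(cross, axis=-1).sum()
    projected = (xmax - xmin) * (ymax - ymin)
    return max(float(area / projected), 1.0)


def _sl(a: int, b: int, shape) -> tuple[slice, slice]:
    return (slice(a, shape[0] - 1 + a), slice(b, shape[1] - 1 + b))
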