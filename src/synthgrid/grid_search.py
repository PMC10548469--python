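"""Systematic rigid-body grid search over probe poses around a host.

The engine enumerates every pose of a rigid probe on an orthogonal 3D grid
around (or above) a rigid host. At each grid point the probe additionally
takes every combination of three Euler rotations about its own centroid; the
nonbonded interaction energy of each pose is evaluated, poses are ranked by
total energy, and the best of them constitute the predicted binding
configurations. Because probes of different searches differ wildly in size
(a molecule vs. a cleaved surface slab), energies are also reported
normalized per probe atom (kcal/atom), which makes molecule-molecule,
molecule-surface and surface-surface searches directly comparable.

The search is exhaustive and fully deterministic: identical inputs give an
identical ranked table. Ties in energy break by grid index, then by
lexicographic rotation angles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .forcefield import Body, EnergyBreakdown, FFParams, body_body_energy

__all__ = [
    "EnergyHistogram",
    "Grid",
    "GridSearchConfigError",
    "Pose",
    "PoseResult",
    "SearchConfig",
    "SearchResult",
    "blend_pair_specs",
    "build_grid",
    "euler_zyx_matrix",
    "normalize_per_atom",
    "pair_matrix",
    "systematic_search",
]


class GridSearchConfigError(ValueError):
    """Invalid search configuration (empty grid, probe too large...)."""


# --------------------------------------------------------------------------
# poses


def euler_zyx_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix for intrinsic z-y'-x'' Euler angles (degrees).

    Columns/rows follow the convention R = Rz(alpha) @ Ry(beta) @ Rx(gamma);
    the matrix acts on column vectors.
    """
    ca, sa = math.cos(math.radians(alpha)), math.sin(math.radians(alpha))
    cb, sb = math.cos(math.radians(beta)), math.sin(math.radians(beta))
    cg, sg = math.cos(math.radians(gamma)), math.sin(math.radians(gamma))
    return np.array([
        [ca * cb, ca * sb * sg - sa * cg, ca * sb * cg + sa * sg],
        [sa * cb, sa * sb * sg + ca * cg, sa * sb * cg - ca * sg],
        [-sb, cb * sg, cb * cg],
    ])


@dataclass(frozen=True)
class Pose:
    """Probe placement: centroid translation (Angstrom, host frame) plus
    three intrinsic z-y-x Euler angles (degrees) about the probe centroid."""

    translation: tuple[float, float, float]
    angles: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(0.0 <= a < 360.0 for a in self.angles):
            raise ValueError("rotation angles must lie in [0, 360)")

    def rotation_matrix(self) -> np.ndarray:
        return euler_zyx_matrix(*self.angles)

    def place(self, centered_xyz: np.ndarray) -> np.ndarray:
        """Apply the pose to probe coordinates already centered on the centroid."""
        return centered_xyz @ self.rotation_matrix().T + np.asarray(self.translation)


# --------------------------------------------------------------------------
# configuration and grid


@dataclass(frozen=True)
class SearchConfig:
    """Grid-search parameters.

    ``extents`` inflates the host bounding box (molecule-host modes) or sets
    the height of the search box above a slab face (surface-host modes).
    ``grid_clash`` drops grid points closer than this to any host atom
    (0 disables); ``clash_factor`` rejects individual poses in which any
    inter-body pair comes closer than ``clash_factor`` times the sum of the
    two vdW radii -- such poses are skipped and counted rather than assigned
    huge repulsive energies, which keeps energy distributions fittable.
    """

    spacing: float = 0.5
    extents: float = 5.0
    angle_increment: float = 30.0
    clash_factor: float = 0.8
    grid_clash: float = 1.0
    top_n: int = 10
    mode: str = "mm"             # "mm" | "ms" | "ss"
    hist_bin: float = 0.005      # kcal/atom

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GridSearchConfigError("grid spacing must be positive")
        n = 360.0 / self.angle_increment
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise GridSearchConfigError("angular increment must divide 360 degrees")
        if self.top_n < 1:
            raise GridSearchConfigError("top_n must be >= 1")
        if self.mode not in ("mm", "ms", "ss"):
            raise GridSearchConfigError(f"unknown search mode {self.mode!r}")

    @property
    def n_rotations_per_axis(self) -> int:
        return int(round(360.0 / self.angle_increment))


@dataclass(frozen=True)
class Grid:
    """Orthogonal grid of candidate probe-centroid positions."""

    points: np.ndarray           # (n, 3), deterministic x-major order
    n_excluded: int              # points dropped by the host-clash rule

    def __len__(self) -> int:
        return len(self.points)


def _axis(lo: float, hi: float, spacing: float) -> np.ndarray:
    n = int(math.floor((hi - lo) / spacing + 1e-9)) + 1
    return lo + spacing * np.arange(max(n, 1))


def build_grid(host: Body, config: SearchConfig) -> Grid:
    """Grid points around a molecular host or above a slab face.

    Molecule modes: the host bounding box inflated by ``extents`` on every
    side. Surface modes: the host footprint in xy, with z running from one
    grid spacing above the top surface atom plane up to ``extents`` above it.
    Points closer than ``grid_clash`` to a host atom are excluded and counted.
    """
    lo, hi = host.bounding_box()
    if config.mode == "mm":
        xs = _axis(lo[0] - config.extents, hi[0] + config.extents, config.spacing)
        ys = _axis(lo[1] - config.extents, hi[1] + config.extents, config.spacing)
        zs = _axis(lo[2] - config.extents, hi[2] + config.extents, config.spacing)
    else:
        z_top = hi[2]
        xs = _axis(lo[0], hi[0], config.spacing)
        ys = _axis(lo[1], hi[1], config.spacing)
        zs = _axis(z_top + config.spacing, z_top + config.extents, config.spacing)
        if len(zs) == 0 or zs[0] <= z_top:
            raise GridSearchConfigError("no grid layer above the surface; increase extents")
    pts = np.array([(x, y, z) for x in xs for y in ys for z in zs])
    n_excluded = 0
    if config.grid_clash > 0:
        d2 = ((pts[:, None, :] - host.xyz[None, :, :]) ** 2).sum(axis=2)
        keep = d2.min(axis=1) >= config.grid_clash ** 2
        n_excluded = int((~keep).sum())
        pts = pts[keep]
    if len(pts) == 0:
        raise GridSearchConfigError("grid is empty after clash exclusion")
    return Grid(pts, n_excluded)


# --------------------------------------------------------------------------
# energy histograms


class EnergyHistogram:
    """Streaming fixed-width histogram (bins anchored at zero)."""

    def __init__(self, bin_width: float) -> None:
        if bin_width <= 0:
            raise ValueError("bin width must be positive")
        self.bin_width = bin_width
        self._counts: dict[int, int] = {}
        self.n = 0

    def add(self, value: float) -> None:
        idx = math.floor(value / self.bin_width)
        self._counts[idx] = self._counts.get(idx, 0) + 1
        self.n += 1

    @property
    def centers(self) -> np.ndarray:
        idx = sorted(self._counts)
        return np.array([(i + 0.5) * self.bin_width for i in idx])

    @property
    def counts(self) -> np.ndarray:
        idx = sorted(self._counts)
        return np.array([self._counts[i] for i in idx], dtype=float)

    @property
    def n_nonempty_bins(self) -> int:
        return len(self._counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center": self.centers, "count": self.counts})


# --------------------------------------------------------------------------
# the search engine


@dataclass(frozen=True)
class PoseResult:
    pose: Pose
    energy: EnergyBreakdown
    per_atom: EnergyBreakdown
    grid_index: int
    angle_index: int


@dataclass
class SearchResult:
    """Ranked outcome of one systematic search."""

    host_label: str
    probe_label: str
    probe_atom_count: int
    config: SearchConfig
    entries: list[PoseResult]
    n_evaluated: int
    n_clashed: int
    n_grid_points: int
    n_grid_excluded: int
    histogram: EnergyHistogram

    @property
    def best(self) -> PoseResult:
        return self.entries[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append({
                "x": e.pose.translation[0], "y": e.pose.translation[1],
                "z": e.pose.translation[2],
                "alpha": e.pose.angles[0], "beta": e.pose.angles[1],
                "gamma": e.pose.angles[2],
                "total": e.energy.total, "vdw": e.energy.dispersive,
                "elec": e.energy.electrostatic, "hbond": e.energy.hbond,
                "total_per_atom": e.per_atom.total,
                "vdw_per_atom": e.per_atom.dispersive,
                "elec_per_atom": e.per_atom.electrostatic,
                "hbond_per_atom": e.per_atom.hbond,
            })
        return pd.DataFrame(rows)


def normalize_per_atom(breakdown: EnergyBreakdown, probe_atom_count: int) -> EnergyBreakdown:
    """Divide every component by the probe atom count (kcal/mol -> kcal/atom)."""
    return breakdown.per_atom(probe_atom_count)


def systematic_search(host: Body, probe: Body, config: SearchConfig,
                      params: FFParams) -> SearchResult:
    """Exhaustive pose enumeration: grid points x rotation triples.

    At each retained grid point the probe is rotated about its centroid by
    every angle triple and translated so its centroid sits on the point; the
    host-probe interaction energy is evaluated and ranked. Clashing poses are
    skipped and counted. The returned entries are the ``top_n`` lowest-energy
    poses in deterministic order.
    """
    host.require_typed()
    probe.require_typed()
    grid = build_grid(host, config)
    if config.mode == "mm":
        probe_size = np.ptp(probe.xyz, axis=0)
        box = grid.points.max(axis=0) - grid.points.min(axis=0)
        if np.any(probe_size > box + 2 * config.spacing):
            raise GridSearchConfigError("probe is larger than the search box")

    inc = config.angle_increment
    nrot = config.n_rotations_per_axis
    angle_values = [i * inc for i in range(nrot)]
    rotations = [
        (euler_zyx_matrix(a, b, g), (a, b, g))
        for a in angle_values for b in angle_values for g in angle_values
    ]

    centered = probe.xyz - probe.centroid()
    # vdW radii from the force field (R0/2 per type), so the clash rule is
    # consistent with the energy model actually in use
    r_host = np.array([params.lookup(t)[1] / 2 for t in host.types])
    r_probe = np.array([params.lookup(t)[1] / 2 for t in probe.types])
    radii_sum = r_host[:, None] + r_probe[None, :]
    clash2 = (config.clash_factor * radii_sum) ** 2

    work = probe._with_xyz(probe.xyz)
    hist = EnergyHistogram(config.hist_bin)
    natoms = len(probe)

    totals: list[float] = []
    keys: list[tuple[int, int]] = []
    breakdowns: list[EnergyBreakdown] = []
    n_clashed = 0

    for gi, point in enumerate(grid.points):
        for ai, (rot, angles) in enumerate(rotations):
            placed = centered @ rot.T + point
            d2 = ((host.xyz[:, None, :] - placed[None, :, :]) ** 2).sum(axis=2)
            if np.any(d2 < clash2):
                n_clashed += 1
                continue
            work.xyz = placed
            e = body_body_energy(host, work, params)
            totals.append(e.total)
            keys.append((gi, ai))
            breakdowns.append(e)
            hist.add(e.total / natoms)

    if not totals:
        raise GridSearchConfigError("every pose clashed; nothing to rank")

    order = sorted(range(len(totals)), key=lambda i: (totals[i], keys[i]))
    entries = []
    for i in order[: config.top_n]:
        gi, ai = keys[i]
        pose = Pose(tuple(grid.points[gi]), rotations[ai][1])
        e = breakdowns[i]
        entries.append(PoseResult(pose, e, e.per_atom(natoms), gi, ai))

    return SearchResult(
        host_label=host.label, probe_label=probe.label,
        probe_atom_count=natoms, config=config, entries=entries,
        n_evaluated=len(totals), n_clashed=n_clashed,
        n_grid_points=len(grid), n_grid_excluded=grid.n_excluded,
        histogram=hist,
    )


# --------------------------------------------------------------------------
# batched pair searches


def blend_pair_specs(api_faces: Sequence[str],
                     excipient_faces: Sequence[str]) -> list[tuple[str, str]]:
    """Ordered (host, probe) label pairs for a two-component blend study.

    All ordered pairs within the API faces (cohesive), all ordered pairs
    across the two materials (adhesive, both orderings since host and probe
    roles are not symmetric for finite slabs), and all ordered pairs within
    the excipient faces (cohesive). Two faces per material gives the
    canonical 4 + 8 + 4 = 16 searches.
    """
    pairs = [(a, b) for a in api_faces for b in api_faces]
    for a in api_faces:
        for b in excipient_faces:
            pairs.append((a, b))
            pairs.append((b, a))
    pairs += [(a, b) for a in excipient_faces for b in excipient_faces]
    return pairs


def pair_matrix(specs: Sequence[tuple[str, str]],
                hosts: Mapping[str, Body],
                probes: Mapping[str, Body],
                config: SearchConfig,
                params: FFParams) -> dict[tuple[str, str], SearchResult]:
    """Run one systematic search per (host label, probe label) spec.

    Duplicate specs are dropped with a warning; results preserve input order.
    """
    seen: set[tuple[str, str]] = set()
    results: dict[tuple[str, str], SearchResult] = {}
    for spec in specs:
        if spec in seen:
            warnings.warn(f"duplicate search spec {spec}; skipping repeat")
            continue
        seen.add(spec)
        host_label, probe_label = spec
        if host_label not in hosts:
            raise KeyError(f"no host body registered under label {host_label!r}")
        if probe_label not in probes:
            raise KeyError(f"no probe body registered under label {probe_label!r}")
        results[spec] = systematic_search(hosts[host_label], probes[probe_label],
                                          config, params)
    return results
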