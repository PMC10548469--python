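"""Independent reference implementations used to cross-check the engine.

These deliberately re-derive grid enumeration, clash rejection, ranking and
tie-breaking with plain Python loops, independent of the vectorized search
engine; pose energies come from the library's energy function, whose own
correctness is checked separately against a pairwise double-loop oracle.
"""

import math

import numpy as np

from synthgrid.forcefield import Body, body_body_energy
from synthgrid.grid_search import euler_zyx_matrix


def brute_force_axis(lo: float, hi: float, spacing: float) -> list[float]:
    n = int(math.floor((hi - lo) / spacing + 1e-9)) + 1
    return [lo + spacing * i for i in range(max(n, 1))]


def brute_force_search(host: Body, probe: Body, config, params):
    """Exhaustive re-enumeration of every pose: list of (total, gi, ai)
    sorted ascending with the engine's documented tie-break, plus the
    clash count."""
    lo = host.xyz.min(axis=0)
    hi = host.xyz.max(axis=0)
    if config.mode == "mm":
        axes = [brute_force_axis(lo[d] - config.extents, hi[d] + config.extents,
                                 config.spacing) for d in range(3)]
    else:
        z_top = hi[2]
        axes = [brute_force_axis(lo[0], hi[0], config.spacing),
                brute_force_axis(lo[1], hi[1], config.spacing),
                brute_force_axis(z_top + config.spacing, z_top + config.extents,
                                 config.spacing)]
    points = [(x, y, z) for x in axes[0] for y in axes[1] for z in axes[2]]
    if config.grid_clash > 0:
        kept = []
        for p in points:
            dmin = min(math.dist(p, tuple(a)) for a in host.xyz)
            if dmin >= config.grid_clash:
                kept.append(p)
        points = kept

    nrot = config.n_rotations_per_axis
    triples = [(a * config.angle_increment, b * config.angle_increment,
                g * config.angle_increment)
               for a in range(nrot) for b in range(nrot) for g in range(nrot)]

    r_host = [params.lookup(t)[1] / 2 for t in host.types]
    r_probe = [params.lookup(t)[1] / 2 for t in probe.types]
    centroid = probe.xyz.mean(axis=0)
    work = Body(probe.elements, probe.xyz, probe.charges, probe.types,
                probe.bonds, probe.units, probe.label, probe.hb_roles)

    ranked = []
    n_clashed = 0
    for gi, point in enumerate(points):
        for ai, angles in enumerate(triples):
            rot = euler_zyx_matrix(*angles)
            placed = (probe.xyz - centroid) @ rot.T + np.asarray(point)
            clash = False
            for i in range(len(host.xyz)):
                for j in range(len(placed)):
                    dx = host.xyz[i, 0] - placed[j, 0]
                    dy = host.xyz[i, 1] - placed[j, 1]
                    dz = host.xyz[i, 2] - placed[j, 2]
                    if dx * dx + dy * dy + dz * dz < (config.clash_factor * (r_host[i] + r_probe[j])) ** 2:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                n_clashed += 1
                continue
            work.xyz = placed
            e = body_body_energy(host, work, params)
            ranked.append((e.total, gi, ai))
    ranked.sort()
    return ranked, n_clashed


def pairwise_energy_loop(body_a: Body, body_b: Body, params):
    """Plain double loop over all cross pairs with scalar arithmetic.

    Mirrors the documented energy model (12-6 vdW with mixing rules, Coulomb,
    12-10 hydrogen bond replacing the donor/acceptor LJ term) without any of
    the vectorized code paths.
    """
    disp_terms, elec_terms, hb_terms = [], [], []
    replaced = set()

    def donors(b):
        nbrs = [[] for _ in range(len(b))]
        for i, j in b.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        out = []
        for h, role in enumerate(b.hb_roles):
            if role == "donor_h":
                heavy = [j for j in nbrs[h] if b.elements[j] != "H"]
                if heavy:
                    out.append((heavy[0], h))
        return out

    def hb(d, h, a):
        rda = math.dist(tuple(d), tuple(a))
        if rda == 0 or rda >= params.hb_cutoff:
            return 0.0
        u1 = np.asarray(d) - np.asarray(h)
        u2 = np.asarray(a) - np.asarray(h)
        c = float(u1 @ u2) / (np.linalg.norm(u1) * np.linalg.norm(u2))
        if c >= 0:
            return 0.0
        s = params.hb_r0 / rda
        return params.hb_depth * (5.0 * s ** 12 - 6.0 * s ** 10) * c ** 4

    for (d, h) in donors(body_a):
        for a in [i for i, r in enumerate(body_b.hb_roles) if r == "acceptor"]:
            e = hb(body_a.xyz[d], body_a.xyz[h], body_b.xyz[a])
            if e != 0.0:
                hb_terms.append(e)
                replaced.add((d, a))
    for (d, h) in donors(body_b):
        for a in [i for i, r in enumerate(body_a.hb_roles) if r == "acceptor"]:
            e = hb(body_b.xyz[d], body_b.xyz[h], body_a.xyz[a])
            if e != 0.0:
                hb_terms.append(e)
                replaced.add((a, d))

    for i in range(len(body_a)):
        for j in range(len(body_b)):
            r = math.dist(tuple(body_a.xyz[i]), tuple(body_b.xyz[j]))
            if r >= params.cutoff:
                continue
            if (i, j) not in replaced:
                d0i, r0i = params.lookup(body_a.types[i])
                d0j, r0j = params.lookup(body_b.types[j])
                d0 = math.sqrt(d0i * d0j)
                r0 = 0.5 * (r0i + r0j) if params.r0_mixing == "arithmetic" else math.sqrt(r0i * r0j)
                s = r0 / r
                disp_terms.append(d0 * (s ** 12 - 2.0 * s ** 6))
            qi = float(body_a.charges[i])
            qj = float(body_b.charges[j])
            elec_terms.append(params.coulomb_k * qi * qj / (params.dielectric * r))
    return math.fsum(disp_terms), math.fsum(elec_terms), math.fsum(hb_terms)
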