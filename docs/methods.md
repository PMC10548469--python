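# Methods

## Scope and model

`synthgrid` predicts interparticle compatibility of crystalline powders by
exhaustive rigid-body sampling: a mobile probe (molecule or cleaved surface
slab) is moved over an orthogonal 3D grid around a stationary host, rotated
about three Euler angles at every grid point, and scored with an atom–atom
nonbonded potential. Binding energies per probe atom feed a cohesive (A–A)
versus adhesive (A–B) comparison that classifies a binary blend as
segregating or dispersing.

All internal units are kcal/mol and Å; kJ appears only at reporting
(×4.184, rounded half-even to 3 decimals for display).

## Energy model

For atoms i, j at distance r on *different* rigid bodies (no intra-body
terms — bodies are rigid):

* dispersive: 12-6 Lennard-Jones, `D0·[(R0/r)¹² − 2(R0/r)⁶]`. Dreiding
  offers both 12-6 and exponential-6 forms; 12-6 is used because it is
  numerically robust against the close contacts that a dense grid scan
  inevitably generates. Unlike pairs mix D0 geometrically and R0
  arithmetically (geometric R0 mixing is available via
  `FFParams(r0_mixing="geometric")`).
* electrostatic: `k_e·q_i·q_j/(ε·r)` with k_e = 332.0637 kcal·Å/(mol·e²)
  and ε = 1 (vacuum). No distance-dependent dielectric.
* hydrogen bond: Dreiding 12-10,
  `D_hb·[5(R_hb/r_DA)¹² − 6(R_hb/r_DA)¹⁰]·cos⁴θ`, evaluated on the
  donor–acceptor distance for D–H···A triples spanning the two bodies,
  active when r_DA < 4.5 Å and the D–H···A angle exceeds 90°. Where active
  it *replaces* the plain Lennard-Jones term of the donor/acceptor heavy
  atom pair. Defaults D_hb = 9.5 kcal/mol, R_hb = 2.75 Å (configurable).

All terms truncate to zero at the nonbond cutoff (default 15 Å, plain
truncation, no switching). Component sums use compensated (`math.fsum`)
summation, which makes every reported energy independent of pair
enumeration order and lets independent enumeration paths agree exactly.

"Polar" energy is the sum of the electrostatic and hydrogen-bond
components, complementing the dispersive part.

### Atom typing and charges

Types follow the Dreiding convention (element + hybridization inferred from
the neighbor count of the covalent-bond graph): e.g. C with four neighbors
→ `C_3`, with three → `C_2`; O with two neighbors → `O_3`; H bonded to
N/O/F → `H__HB` and acts as a hydrogen-bond donor; N/O/F atoms act as
acceptors. The packaged vdW table (`data/dreiding_vdw.csv`) carries
Dreiding-style D0/R0 values for the common organic elements plus
alkali/halide entries.

Partial charges default to a built-in Gasteiger-type iterative partial
equalization of orbital electronegativity (PEOE, 8 damped iterations, all
bonds treated as single). Alternatives: a per-element charge table
(`charge_scheme="table"`) or all-zero charges. Per-molecular-unit formal
charges (for salts, e.g. +1/+1/−2) are enforced by a uniform shift after
the scheme runs. Every result manifest records the scheme used; quantitative
energies depend on it, orderings are far less sensitive.

## Crystal structures and surfaces

CIF input is read through gemmi (core dictionary tags, first data block,
"(esd)" suffixes stripped; sites with occupancy < 1 are rejected — disorder
is out of scope). Symmetry expansion folds coordinates to [0,1) and merges
duplicate images at 1e-3 Å. Molecular units are connected components of the
covalent-bond graph (bond when d < 1.15 × sum of covalent radii, minimum
image); units are unwrapped across cell boundaries so every molecule is
whole. A covalent network that wraps the cell (an extended solid) is
rejected. The Cartesian convention everywhere: a along +x, b in the
xy-plane, right-handed.

### Surface alignment

For a face (h k l) (gcd-reduced, first nonzero index positive) the lattice
is re-described by a unimodular integer recombination of the cell vectors:
two new vectors span the (hkl) plane (built from extended-gcd identities),
the third satisfies h·t₁+k·t₂+l·t₃ = 1 and therefore advances exactly one
d-spacing along the plane normal. The frame is rotated so the normal is +z;
in-plane vectors then have exactly zero z-component, and cell volume and
atom content are preserved. Because {0 k 0}-type sub-layering is handled by
the termination scan (below), Miller indices are always stored reduced; an
absent (010) reflection simply makes the scan find the half-d-spaced cut.

### Lattice, slice and attachment energies

The lattice energy is a direct half-sum of the interactions between each
molecular unit of the home cell and all whole units within a summation
region, divided by the number of symmetry operators (per asymmetric unit;
for a P1 re-description this is per cell content). Two truncation modes:

* `radius` (default 25 Å): whole units whose centroid lies within the
  radius — charge-neutral *group* truncation for molecular crystals; a
  convergence probe (the same sum over a region one cell smaller) is
  reported with the result.
* `cell_shells`: all complete unit cells within an n-shell cube — the
  correct neutral-shell truncation for ionic lattices. A rock-salt toy
  crystal summed this way reproduces the Madelung constant 1.7476 to 0.003%
  at 4 shells, which is the packaged electrostatics oracle.

Pair-level truncation inside the sum follows the force-field cutoff; pass an
infinite cutoff to make group selection the only truncation (used for the
Madelung check; also how the nearest-neighbor-only hand counts set their
cutoff between the first and second neighbor shell).

Growth layers for a face are slabs of thickness d_hkl with boundaries at
z = (offset + m)·d. A unit belongs to the layer containing its centroid —
units are never cut. E_slice counts neighbors in the central unit's own
layer, E_att those in all other layers; E_latt is summed independently over
the whole environment so the identity E_latt = E_slice + E_att is a genuine
internal check (verified to 1e-6 relative in the tests). A 1e-9 epsilon in
the layer assignment keeps units whose centroid falls exactly on a boundary
(and all their periodic images) consistently in the layer above; without it,
float cancellation at such degenerate offsets can misclassify a single
image.

The termination scan evaluates offsets 0, 0.1, …, 0.9 (step must divide one
d-spacing evenly) and selects the minimum |E_att|, ties going to the
smallest offset. Because E_att is piecewise constant between offsets where
a centroid crosses a boundary, the 0.1 grid finds the same plateau as an
exhaustive 0.01 scan.

### BFDH and slabs

Faces with |h|,|k|,|l| ≤ 3 (configurable bound) are ranked by descending
interplanar spacing; reflections systematically absent under the stored
operators (screw axes, glides, centering) are scored by the first allowed
multiple, the standard BFDH demotion. Families are grouped by the rotational
parts of the stored operators plus Friedel pairing, one representative each.

Slabs are finite (non-periodic) bodies: the aligned cell is replicated
in-plane and stacked downward from the selected cut; a one-layer slab is
the "first molecular layer" probe surface. Exposed area = in-plane cell
area × repeats. Rugosity is the ratio of the triangulated top-surface area
of a vdW-sphere height map (default grid 0.2 Å; uncovered grid points take
the lowest covered height) to the projected footprint area; it is ≥ 1 by
construction and ~1.4 for the toy slabs here, in the range typical of AFM
measurements on pharmaceutical crystals.

## The search engine

Grid: host bounding box inflated by `extents` on every side (molecule-host
modes), or the host footprint with z from one spacing above the top surface
atom plane up to `extents` above it (surface-host modes). Points closer
than `grid_clash` (default 1 Å) to a host atom are dropped and counted.
Rotations: intrinsic z-y-x Euler angles about the probe centroid, default
increment 30° (tests and the acceptance study use coarser increments; the
enumeration is exhaustive, so cost scales with the cube of the rotation
count). Defaults of 0.5 Å spacing for molecular probes and 1.0–1.5 Å for
slab probes balance resolution against pose count.

Poses in which any inter-body pair comes closer than 0.8 × the sum of the
two vdW radii are skipped and counted rather than scored; assigning huge
repulsive energies instead would poison the energy distributions that the
Gaussian fits consume. The vdW radii here are R0/2 of the force-field types
actually in use, keeping the clash criterion consistent with the energy
model (element-table radii would disagree with custom toy types).

Ranking is by total energy with deterministic tie-breaks (grid index, then
lexicographic angles); identical inputs give byte-identical result tables.
Per-atom normalization divides every component by the probe atom count, so
molecule and slab probes report on a common kcal/atom scale. Energy
distributions are kept as streaming fixed-width histograms (default bin
0.005 kcal/atom) rather than storing every pose.

The engine is validated against an independent brute-force enumerator
(plain Python loops, separate ranking) with *exact* equality of the ranked
(energy, grid index, rotation index) lists on randomized instances — the
compensated summation above is what makes exactness attainable.

## Blend statistics and verdict

Each search contributes one binding energy: the minimum (most negative)
total over all poses, per probe atom — the natural reading of "best binding
configuration". Groups of searches (cohesive A–A, adhesive A–B, cohesive
B–B; by default one search per face pair, i.e. aggregation over faces)
yield means and sample standard deviations (n−1; zero for a single
search). Gaussian fits to binned distributions use least squares with
moment-based initialization; histograms with fewer than three nonempty bins
fall back to weighted moments with a flag.

The verdict compares mean cohesive (API–API) against mean adhesive
(API–excipient, both host/probe orderings averaged). Cohesion stronger by
more than the margin threshold (default 0.01 kcal/atom) → cohesively
balanced, segregation predicted. Otherwise — adhesion dominant *or* the two
within the margin — adhesively balanced: near-equal cohesion and adhesion
gives fines no energetic reason to pile onto themselves rather than spread
over the carrier, which is the dispersed outcome observed for
excipient-fines blends. The margin is always reported so the threshold can
be revisited.

## Toy structures: what they emulate and what they do not

The generators reproduce the *structural features* that exercise every code
path: P1 and P2₁ (screw-axis) cells, neutral molecular crystals, hydrogen
bond donors/acceptors, a hydrate-like water, a tri-ionic (2 cation +
1 divalent anion) asymmetric unit, and analytic lattices (simple-cubic
Lennard-Jones, rock salt) whose energies are hand-computable. They do not
mimic any real compound's coordinates, so passing tests demonstrates
correctness of the machinery — symmetry handling, lattice sums, search,
statistics — not quantitative transferability to a particular drug or
excipient, which additionally depends on the charge model and force-field
parameterization chosen for that system.

Problem sizes in the packaged study were chosen to keep the full pipeline
interactive: 3×3×2-cell host slabs against 2×2×1 probe slabs, 1.5 Å grid
spacing, 120° rotation increments (16 searches, a few thousand scored poses
in total), lattice sums to 12–14 Å on ~5 Å cells and 4 neutral shells for
the Madelung check. All are parameters, not constants.

## Known limitations

* Direct sums only (no Ewald): charged or strongly dipolar lattices must be
  summed over neutral groups; conditional convergence is diagnosed, not
  eliminated.
* No surface relaxation, reconstruction, disorder or amorphous content;
  terminations come from the bulk structure.
* Rigid bodies: no pose minimization, no flexible probes, no many-body
  effects, no polarizability.
* The Gasteiger-type charges are a generic default; systems dominated by
  ionic interactions deserve a bespoke charge table (supported via
  `charge_scheme="table"`).
* BFDH ranks faces purely geometrically (with extinction demotion); no
  growth-rate or energy-based morphology beyond the attachment-energy
  termination selection.
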