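import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from synthgrid.crystal_structures import AtomSite, CrystalStructure, UnitCell
from synthgrid.forcefield import Body
from synthgrid.fixtures import toy_params

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Toy-type parameter table with the default cutoff."""
    return toy_params()


@pytest.fixture
def lj_pair_bodies():
    """Two single-atom Lennard-Jones bodies (D0=1, R0=2) for dimer checks."""
    host = Body(["Ar"], [[0.0, 0.0, 0.0]], charges=[0.0], types=["LJ"], label="host")
    probe = Body(["Ar"], [[0.0, 0.0, 0.0]], charges=[0.0], types=["LJ"], label="probe")
    return host, probe, toy_params({"LJ": (1.0, 2.0)})


@pytest.fixture(scope="session")
def bilayer_crystal():
    """P1 molecular crystal with two diatomics per cell at unequal heights.

    The pair at z = 0.15c and z = 0.55c forms a tightly bound bilayer; the
    gap to the next cell's bilayer is wider, so terminations that cut between
    the two molecules of a bilayer have a distinctly larger |E_att| than cuts
    through the wide gap. Molecules lie along x so no interatomic contact is
    shorter than the vdW minimum.
    """
    cell = UnitCell(5.0, 5.0, 8.0)
    dx = 0.55 / 5.0
    sites = []
    for i, zc in enumerate((0.15, 0.55)):
        sites.append(AtomSite("N", f"M{i}A", np.array([0.25 - dx, 0.25, zc]),
                              charge=0.0, ff_type="TOY_A"))
        sites.append(AtomSite("N", f"M{i}B", np.array([0.25 + dx, 0.25, zc]),
                              charge=0.0, ff_type="TOY_A"))
    return CrystalStructure(cell, sites, spacegroup="P 1")


def random_charged_body(rng: np.random.Generator, natoms: int, label: str,
                        spread: float = 2.5, polar: bool = True) -> Body:
    """Random rigid test body with zero net charge and toy atom types."""
    xyz = rng.uniform(-spread / 2, spread / 2, size=(natoms, 3))
    # keep atoms at least 0.8 A apart so no accidental singularities
    for i in range(1, natoms):
        for _ in range(50):
            d = np.linalg.norm(xyz[:i] - xyz[i], axis=1).min()
            if d > 0.8:
                break
            xyz[i] = rng.uniform(-spread / 2, spread / 2, size=3)
    if polar:
        q = rng.normal(0, 0.2, natoms)
        q -= q.mean()
    else:
        q = np.zeros(natoms)
    types = list(rng.choice(["TOY_A", "TOY_B"], natoms))
    elements = ["N" if t == "TOY_A" else "O" for t in types]
    return Body(elements, xyz, charges=q, types=types, label=label)
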