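import numpy as np
import pytest
from hypothesis import settings

from mwablate.geometry import AntennaGeometry, SimulationDomain
from mwablate.materials import MaterialModelParams
from mwablate.mesh import structured_mesh

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return MaterialModelParams()


def make_box_domain(r0, r1, z0, z1, nr, nz, wall=(), cooling=()):
    """Plain rectangular tissue domain in (r, z) for thermal unit tests.

    ``wall``/``cooling`` select boundary sides from {'bottom','top','left',
    'right'} to tag as fixed-temperature / convective-cooling edge sets.
    """
    mesh = structured_mesh(np.linspace(r0, r1, nr + 1), np.linspace(z0, z1, nz + 1))
    bedges = mesh.boundary_edges(np.ones(mesh.n_elements, bool))
    mid = 0.5 * (mesh.nodes[bedges[:, 0]] + mesh.nodes[bedges[:, 1]])
    tol = 1e-12
    side = {
        "bottom": mid[:, 1] < z0 + tol,
        "top": mid[:, 1] > z1 - tol,
        "left": mid[:, 0] < r0 + tol,
        "right": mid[:, 0] > r1 - tol,
    }
    def collect(names):
        if not names:
            return bedges[:0]
        sel = np.zeros(len(bedges), bool)
        for nm in names:
            sel |= side[nm]
        return bedges[sel]
    mesh.edges["wall"] = collect(wall)
    mesh.edges["cooling"] = collect(cooling)
    return SimulationDomain(mesh=mesh, geometry=AntennaGeometry(),
                            z_tip=z0, z_slot=0.5 * (z0 + z1), extents=(r1, z1))
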