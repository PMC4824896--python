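import numpy as np
import pytest

import whaleram as wr


@pytest.fixture(scope="session")
def model_a_geometry():
    return wr.build_head_profile(variant="A")


@pytest.fixture(scope="session")
def model_a_mesh(model_a_geometry):
    return wr.generate_mesh(model_a_geometry, 0.1)


@pytest.fixture(scope="session")
def junk_load(model_a_mesh):
    return wr.make_load_case(model_a_mesh, "junk_full")


@pytest.fixture(scope="session")
def model_a_solution():
    return wr.solve_variant("A", target_h=0.1)


@pytest.fixture(scope="session")
def small_null_populations():
    """Two Monte Carlo populations from the identical model on a coarse mesh."""
    geom = wr.build_head_profile(variant="A")
    mesh = wr.generate_mesh(geom, 0.25)
    lc = wr.make_load_case(mesh, "junk_full")
    pop_a = wr.run_monte_carlo(mesh, lc, n_iter=20, cv=0.10, seed=11)
    pop_b = wr.run_monte_carlo(mesh, lc, n_iter=20, cv=0.10, seed=12)
    return mesh, lc, pop_a, pop_b


def cantilever_solution(ny=20, L=10.0, depth=1.0, E=1.0e7, P=1.0):
    """Slender cantilever: left edge clamped, uniform shear load on the tip."""
    geom = wr.rectangle_geometry(L, depth)
    mesh = wr.generate_mesh(geom, depth / ny)
    bcs = wr.BoundaryConditions.fix_segment(mesh, "left")
    mats = {"plate": wr.Material(E, 0.0)}
    edges = mesh.edges_with_label("right")
    d = mesh.nodes[edges[:, 1]] - mesh.nodes[edges[:, 0]]
    lengths = np.hypot(d[:, 0], d[:, 1])
    f = np.zeros(2 * mesh.n_nodes)
    for (a, b), ln in zip(edges, lengths):
        share = 0.5 * P * ln / lengths.sum()
        f[2 * a + 1] -= share
        f[2 * b + 1] -= share
    u = wr.solve(mesh, mats, bcs, f, thickness=1.0)
    return mesh, mats, bcs, f, u
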