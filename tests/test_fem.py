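"""Solver verification: element stiffness, patch test, cantilever benchmark,
equilibrium, linearity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import whaleram as wr
from whaleram.fem import Material, SolverError, element_stiffness, _b_matrices
from whaleram.geometry import rectangle_geometry

from conftest import cantilever_solution


def brute_force_stiffness(coords, material, thickness, n=120):
    """Independent oracle: K = t * integral(B^T D B) by midpoint quadrature
    over a uniform barycentric subdivision, with shape-function gradients
    obtained numerically from the nodal linear system."""
    coords = np.asarray(coords, float)
    # linear shape functions: N_i(x, y) = a + b x + c y with N_i(x_j) = delta_ij
    A = np.column_stack([np.ones(3), coords])
    grads = np.linalg.solve(A, np.eye(3))[1:, :].T  # (3 nodes, 2)
    B = np.zeros((3, 6))
    for i in range(3):
        B[0, 2 * i] = grads[i, 0]
        B[1, 2 * i + 1] = grads[i, 1]
        B[2, 2 * i] = grads[i, 1]
        B[2, 2 * i + 1] = grads[i, 0]
    D = material.d_matrix()
    integrand = B.T @ D @ B
    # midpoint quadrature over n^2 congruent subtriangles
    area_total = 0.0
    K = np.zeros((6, 6))
    v0, v1, v2 = coords
    e1, e2 = v1 - v0, v2 - v0
    sub_area = abs(e1[0] * e2[1] - e1[1] * e2[0]) / (2 * n * n)
    for i in range(n):
        for j in range(n - i):
            area_total += sub_area
            K += integrand * sub_area
            if j < n - i - 1:
                area_total += sub_area
                K += integrand * sub_area
    return thickness * K


def test_element_stiffness_matches_quadrature_oracle():
    """Unit right triangle, E = 1, nu = 0, t = 1."""
    coords = [(0, 0), (1, 0), (0, 1)]
    mat = Material(1.0, 0.0)
    K = element_stiffness(coords, mat, 1.0)
    K_ref = brute_force_stiffness(coords, mat, 1.0)
    assert np.allclose(K, K_ref, rtol=1e-12, atol=1e-14)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    pts=st.lists(
        st.tuples(
            st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False)
        ),
        min_size=3,
        max_size=3,
    ),
    E=st.floats(1e3, 1e11),
    nu=st.floats(0.0, 0.45),
)
def test_element_stiffness_symmetry_and_nullspace(pts, E, nu):
    coords = np.array(pts)
    v1, v2 = coords[1] - coords[0], coords[2] - coords[0]
    area = 0.5 * (v1[0] * v2[1] - v1[1] * v2[0])
    if area < 1e-3:  # skip (near-)degenerate draws
        return
    K = element_stiffness(coords, Material(E, nu), 0.1)
    assert np.allclose(K, K.T, rtol=1e-12)
    # rigid translations and rotation are zero-energy
    tx = np.array([1, 0, 1, 0, 1, 0], float)
    ty = np.array([0, 1, 0, 1, 0, 1], float)
    rot = np.column_stack([-coords[:, 1], coords[:, 0]]).ravel()
    scale = np.abs(K).max()
    for v in (tx, ty, rot):
        assert np.abs(K @ v).max() < 1e-10 * scale * max(1, np.abs(v).max())
    # exactly a 3-dimensional nullspace
    w = np.linalg.eigvalsh(K)
    assert np.sum(w < 1e-9 * w[-1]) == 3
    assert np.all(w > -1e-9 * w[-1])


def test_degenerate_triangle_rejected():
    with pytest.raises(SolverError, match="degenerate"):
        element_stiffness([(0, 0), (1, 1), (2, 2)], Material(1e9, 0.3))


def test_material_validation():
    with pytest.raises(ValueError):
        Material(-1.0, 0.3)
    with pytest.raises(ValueError):
        Material(1e9, 0.5)


def _uniaxial_plate(nx_ny=(8, 4), sigma0=1.0e6, E=5e9, nu=0.3):
    geom = rectangle_geometry(2.0, 1.0)
    mesh = wr.generate_mesh(geom, 0.25)
    mats = {"plate": Material(E, nu)}
    bcs_nodes = mesh.nodes_on_segment("left")
    # roller left edge: fix u_x everywhere, u_y at one corner node
    # (simplest patch setup: fully clamp the left edge would disturb the
    # uniform state through Poisson contraction, so use nu-consistent BCs)
    return mesh, mats, sigma0


def test_patch_uniform_tension_exact():
    """Uniform traction on the right edge of a clamped-roller rectangle
    reproduces the constant stress state to machine precision."""
    mesh, mats, sigma0 = _uniaxial_plate()
    t = 0.1
    nodes = mesh.nodes
    left = mesh.nodes_on_segment("left")
    # constrain u_x on the left edge; pin u_y of the bottom-left corner
    corner = left[np.argmin(nodes[left, 1])]
    fixed = left
    values = np.zeros((len(fixed), 2))
    free_y = np.ones(len(fixed), bool)
    free_y[np.where(fixed == corner)[0]] = False
    # emulate mixed constraints by solving with u_y released on the left
    # edge except the corner: build the reduced system directly
    from whaleram.fem import LinearSystem, StiffnessDecomposition

    decomp = StiffnessDecomposition(mesh, mats, thickness=t)
    f = np.zeros(decomp.ndof)
    edges = mesh.edges_with_label("right")
    d = nodes[edges[:, 1]] - nodes[edges[:, 0]]
    lengths = np.hypot(d[:, 0], d[:, 1])
    for (a, b), ln in zip(edges, lengths):
        share = 0.5 * sigma0 * t * ln
        f[2 * a] += share
        f[2 * b] += share
    K = decomp.matrix()
    fixed_dofs = np.concatenate([2 * fixed, [2 * corner + 1]])
    free = np.ones(decomp.ndof, bool)
    free[fixed_dofs] = False
    import scipy.sparse.linalg as spl

    u = np.zeros(decomp.ndof)
    u[free] = spl.spsolve(K[free][:, free].tocsc(), f[free])
    stress = wr.recover_stresses(
        mesh, wr.DisplacementField(u.reshape(-1, 2)), mats
    )
    assert np.allclose(stress.sxx, sigma0, rtol=1e-10)
    assert np.abs(stress.syy).max() < 1e-10 * sigma0
    assert np.abs(stress.txy).max() < 1e-10 * sigma0


def test_cantilever_tip_deflection_euler_bernoulli():
    """Slender cantilever (L/h = 10), >= 20 elements through the depth:
    tip deflection within 5% of PL^3/3EI."""
    L, depth, E, P = 10.0, 1.0, 1.0e7, 1.0
    mesh, mats, bcs, f, u = cantilever_solution(ny=20, L=L, depth=depth, E=E, P=P)
    I = depth**3 / 12
    exact = P * L**3 / (3 * E * I)
    tip = -u.u[np.isclose(mesh.nodes[:, 0], L), 1].mean()
    assert tip == pytest.approx(exact, rel=0.05)


def test_zero_load_zero_displacement(model_a_mesh):
    bcs = wr.BoundaryConditions.fix_segment(model_a_mesh, "posterior")
    u = wr.solve(
        model_a_mesh, wr.DEFAULT_MATERIALS, bcs,
        np.zeros(2 * model_a_mesh.n_nodes),
    )
    assert np.abs(u.u).max() == 0.0


def test_global_equilibrium(model_a_solution):
    """Reactions equal minus the applied load to 1e-8 relative."""
    sol = model_a_solution
    applied = sol.load_case.total_vector()
    assert np.allclose(
        sol.reactions, -applied, atol=1e-8 * np.linalg.norm(applied)
    )


def test_linearity_in_load(model_a_mesh):
    mesh = model_a_mesh
    bcs = wr.BoundaryConditions.fix_segment(mesh, "posterior")
    lc1 = wr.make_load_case(mesh, "junk_full", total_force=1.0e5)
    lc2 = wr.make_load_case(mesh, "junk_full", total_force=2.0e5)
    u1 = wr.solve(mesh, wr.DEFAULT_MATERIALS, bcs, lc1)
    u2 = wr.solve(mesh, wr.DEFAULT_MATERIALS, bcs, lc2)
    assert np.allclose(2 * u1.u, u2.u, rtol=1e-9, atol=1e-15)
    s1 = wr.recover_stresses(mesh, u1, wr.DEFAULT_MATERIALS)
    s2 = wr.recover_stresses(mesh, u2, wr.DEFAULT_MATERIALS)
    assert np.allclose(2 * s1.von_mises, s2.von_mises, rtol=1e-9)


def test_compliance_increases_under_refinement():
    """CST is overly stiff; refinement monotonically releases strain energy
    on the bending benchmark."""
    energies = []
    for ny in (5, 10, 20):
        mesh, mats, bcs, f, u = cantilever_solution(ny=ny)
        energies.append(float(f @ u.flat()))
    assert energies[0] < energies[1] < energies[2]


def test_stress_invariants_trivial_states():
    s = wr.StressField(
        sxx=np.array([2.0, 0.0, 3.0]),
        syy=np.array([0.0, 0.0, 3.0]),
        txy=np.array([0.0, 1.5, 0.0]),
    )
    vm = s.von_mises
    assert vm[0] == pytest.approx(2.0)                 # uniaxial
    assert vm[1] == pytest.approx(np.sqrt(3) * 1.5)    # pure shear
    assert vm[2] == pytest.approx(3.0)                 # equibiaxial
    p_max, p_min = s.principal()
    assert p_max[2] == pytest.approx(3.0) and p_min[2] == pytest.approx(3.0)
    assert np.all(p_max >= p_min)
    assert np.all(vm >= 0)


def test_missing_material_rejected(model_a_mesh):
    bcs = wr.BoundaryConditions.fix_segment(model_a_mesh, "posterior")
    mats = {k: v for k, v in wr.DEFAULT_MATERIALS.items() if k != "organ"}
    with pytest.raises(SolverError, match="organ"):
        wr.solve(model_a_mesh, mats, bcs, np.zeros(2 * model_a_mesh.n_nodes))


def test_empty_fixed_set_rejected():
    with pytest.raises(SolverError, match="empty"):
        wr.BoundaryConditions(fixed_nodes=np.array([], dtype=int))
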