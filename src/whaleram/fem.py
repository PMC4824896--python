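"""Plane-stress linear elastostatics on triangulated domains.

Constant-strain (3-node) triangles, direct sparse factorisation, exact
row/column elimination of Dirichlet constraints so reaction recovery is
clean.  The head is a thin 0.1 m slab, hence plane stress; all forces are
per full slab thickness (N, not N/m).

The per-material stiffness decomposition K = sum_g E_g * Khat_g (unit-modulus
matrices per material group) makes re-solving under sampled stiffnesses cheap,
which the Monte Carlo machinery in :mod:`whaleram.stats` relies on.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import Mesh

log = logging.getLogger(__name__)

DEFAULT_THICKNESS = 0.1  # m, the slab width


class SolverError(RuntimeError):
    """Raised for singular systems or invalid solver inputs."""


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material: Young's modulus (Pa), Poisson ratio."""

    E: float
    nu: float

    def __post_init__(self):
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be > 0, got {self.E}")
        if not 0 <= self.nu < 0.5:
            raise ValueError(f"Poisson ratio must be in [0, 0.5), got {self.nu}")

    def d_matrix(self) -> np.ndarray:
        """Plane-stress constitutive matrix (3x3)."""
        E, nu = self.E, self.nu
        return (E / (1 - nu**2)) * np.array(
            [[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]]
        )


#: nominal tissue properties: skull bone, connective tissue (partitions and
#: the fibrous case), and the oil/wax mixture of organ and junk
DEFAULT_MATERIALS: dict[str, Material] = {
    "skull": Material(14.8e9, 0.1),
    "partition": Material(2.0e9, 0.2),
    "case": Material(2.0e9, 0.2),
    "organ": Material(1.0e9, 0.49),
    "junk_oil": Material(1.0e9, 0.49),
}

#: the three stiffness groups sampled by the Monte Carlo procedure
MATERIAL_GROUPS: dict[str, tuple[str, ...]] = {
    "skull": ("skull",),
    "connective_tissue": ("partition", "case"),
    "oil_wax": ("organ", "junk_oil"),
}


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet constraints: nodes with prescribed displacements.

    ``values`` holds the prescribed (u_x, u_y) per fixed node (zeros for the
    no-displacement posterior constraint of the ramming analyses).
    """

    fixed_nodes: np.ndarray
    values: np.ndarray | None = None

    def __post_init__(self):
        if len(self.fixed_nodes) == 0:
            raise SolverError("fixed node set is empty: system would be singular")
        if self.values is not None and self.values.shape != (
            len(self.fixed_nodes),
            2,
        ):
            raise SolverError("values must be (n_fixed, 2)")

    @classmethod
    def fix_segment(cls, mesh: Mesh, labels="posterior") -> "BoundaryConditions":
        nodes = mesh.nodes_on_segment(labels)
        if nodes.size == 0:
            raise SolverError(f"no boundary nodes on segment(s) {labels!r}")
        return cls(fixed_nodes=nodes)

    def dof_values(self, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
        dofs = np.repeat(self.fixed_nodes * 2, 2) + np.tile(
            [0, 1], len(self.fixed_nodes)
        )
        vals = (
            np.zeros(2 * len(self.fixed_nodes))
            if self.values is None
            else self.values.ravel()
        )
        return dofs, vals


@dataclass(frozen=True)
class DisplacementField:
    """Per-node displacement (u_x, u_y) in metres."""

    u: np.ndarray  # (N, 2)

    def flat(self) -> np.ndarray:
        return self.u.ravel()


@dataclass(frozen=True)
class StressField:
    """Element-wise plane-stress state (Pa).

    Components sigma_xx, sigma_yy, tau_xy plus derived von Mises
    ``sqrt(sxx^2 - sxx*syy + syy^2 + 3*txy^2)`` and principal stresses.
    """

    sxx: np.ndarray
    syy: np.ndarray
    txy: np.ndarray

    @property
    def von_mises(self) -> np.ndarray:
        return np.sqrt(
            self.sxx**2 - self.sxx * self.syy + self.syy**2 + 3 * self.txy**2
        )

    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        c = 0.5 * (self.sxx + self.syy)
        r = np.sqrt((0.5 * (self.sxx - self.syy)) ** 2 + self.txy**2)
        return c + r, c - r

    @property
    def p_max(self) -> np.ndarray:
        return self.principal()[0]

    @property
    def p_min(self) -> np.ndarray:
        return self.principal()[1]


def _b_matrices(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Strain-displacement matrices B (E, 3, 6) and signed areas (E,)."""
    c = mesh.element_coords()
    x, y = c[..., 0], c[..., 1]
    # b_i = y_j - y_k, c_i = x_k - x_j (cyclic)
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    g = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = 0.5 * (b[:, 0] * g[:, 1] - b[:, 1] * g[:, 0])
    # B rows: [eps_xx, eps_yy, gamma_xy]; columns ordered (u1x,u1y,...,u3y)
    E = len(c)
    B = np.zeros((E, 3, 6))
    inv2A = 1.0 / (2 * area)
    for i in range(3):
        B[:, 0, 2 * i] = b[:, i] * inv2A
        B[:, 1, 2 * i + 1] = g[:, i] * inv2A
        B[:, 2, 2 * i] = g[:, i] * inv2A
        B[:, 2, 2 * i + 1] = b[:, i] * inv2A
    return B, area


def element_stiffness(
    triangle_coords: np.ndarray,
    material: Material,
    thickness: float = DEFAULT_THICKNESS,
) -> np.ndarray:
    """6x6 constant-strain-triangle stiffness, K = A * t * B^T D B.

    Dof ordering (u1x, u1y, u2x, u2y, u3x, u3y).  Raises for degenerate
    (non-positive-area) triangles.
    """
    c = np.asarray(triangle_coords, float)
    x, y = c[:, 0], c[:, 1]
    area = 0.5 * (
        (x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0])
    )
    if area <= 0:
        raise SolverError(f"degenerate triangle (signed area {area:.3e})")
    b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
    g = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
    B = np.zeros((3, 6))
    B[0, 0::2] = b / (2 * area)
    B[1, 1::2] = g / (2 * area)
    B[2, 0::2] = g / (2 * area)
    B[2, 1::2] = b / (2 * area)
    return area * thickness * B.T @ material.d_matrix() @ B


class StiffnessDecomposition:
    """Global stiffness split into unit-modulus matrices per material group.

    ``K(E_by_group) = sum_g E_g * Khat_g`` with Khat_g assembled at E = 1 and
    the group's actual Poisson ratio.  Groups with differing Poisson ratios
    among their labels are rejected.
    """

    def __init__(
        self,
        mesh: Mesh,
        materials: Mapping[str, Material],
        groups: Mapping[str, Sequence[str]] | None = None,
        thickness: float = DEFAULT_THICKNESS,
    ):
        labels_present = set(np.unique(mesh.element_material))
        missing = labels_present - set(materials)
        if missing:
            raise SolverError(f"no material for region label(s) {sorted(missing)}")
        if groups is None:
            groups = {lab: (lab,) for lab in sorted(labels_present)}
        self.mesh = mesh
        self.thickness = thickness
        self.materials = dict(materials)
        self.groups = {
            g: tuple(l for l in labs if l in labels_present)
            for g, labs in groups.items()
        }
        self.groups = {g: labs for g, labs in self.groups.items() if labs}
        self.nominal = {}
        for g, labs in self.groups.items():
            nus = {materials[l].nu for l in labs}
            Es = {materials[l].E for l in labs}
            if len(nus) > 1 or len(Es) > 1:
                raise SolverError(
                    f"material group {g!r} mixes different properties"
                )
            self.nominal[g] = materials[labs[0]].E

        B, area = _b_matrices(mesh)
        if np.any(area <= 0):
            bad = int(np.argmin(area))
            raise SolverError(f"degenerate element {bad}")
        self._B, self._area = B, area
        n = mesh.n_nodes
        self.ndof = 2 * n
        tri = mesh.triangles
        edofs = np.empty((mesh.n_elements, 6), dtype=np.int64)
        edofs[:, 0::2] = 2 * tri
        edofs[:, 1::2] = 2 * tri + 1
        rows = np.repeat(edofs, 6, axis=1).ravel()
        cols = np.tile(edofs, (1, 6)).ravel()

        self.khat: dict[str, sp.csr_matrix] = {}
        for g, labs in self.groups.items():
            sel = np.isin(mesh.element_material, list(labs))
            Dhat = Material(1.0, materials[labs[0]].nu).d_matrix()
            ke = np.einsum(
                "eji,jk,ekl,e->eil", B[sel], Dhat, B[sel], area[sel] * thickness
            )
            e_rows = rows.reshape(-1, 36)[sel].ravel()
            e_cols = cols.reshape(-1, 36)[sel].ravel()
            self.khat[g] = sp.coo_matrix(
                (ke.ravel(), (e_rows, e_cols)), shape=(self.ndof, self.ndof)
            ).tocsr()

    def matrix(self, moduli: Mapping[str, float] | None = None) -> sp.csr_matrix:
        moduli = dict(moduli or {})
        K = None
        for g, Khat in self.khat.items():
            Eg = moduli.get(g, self.nominal[g])
            K = Eg * Khat if K is None else K + Eg * Khat
        return K

    def element_moduli(self, moduli: Mapping[str, float] | None = None) -> np.ndarray:
        """Per-element Young's modulus under (possibly sampled) group moduli."""
        moduli = dict(moduli or {})
        E = np.empty(self.mesh.n_elements)
        for g, labs in self.groups.items():
            sel = np.isin(self.mesh.element_material, list(labs))
            E[sel] = moduli.get(g, self.nominal[g])
        return E


class LinearSystem:
    """Constrained linear system with cached structure for repeated solves."""

    def __init__(
        self,
        decomp: StiffnessDecomposition,
        bcs: BoundaryConditions,
    ):
        self.decomp = decomp
        self.bcs = bcs
        ndof = decomp.ndof
        fixed_dofs, fixed_vals = bcs.dof_values(decomp.mesh.n_nodes)
        self.fixed_dofs = fixed_dofs
        self.fixed_vals = fixed_vals
        free = np.ones(ndof, dtype=bool)
        free[fixed_dofs] = False
        self.free = free

    def solve(
        self,
        f: np.ndarray,
        moduli: Mapping[str, float] | None = None,
    ) -> tuple[np.ndarray, sp.csr_matrix]:
        """Solve K u = f under the constraints; returns (u, K)."""
        K = self.decomp.matrix(moduli)
        free = self.free
        u = np.zeros(self.decomp.ndof)
        u[self.fixed_dofs] = self.fixed_vals
        # constrained values in ascending dof order to match K's columns
        rhs = f[free] - K[free][:, ~free] @ u[~free]
        Kff = K[free][:, free].tocsc()
        try:
            lu = splu(Kff)
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise SolverError(f"stiffness factorisation failed: {exc}") from exc
        u[free] = lu.solve(rhs)
        if not np.all(np.isfinite(u)):
            raise SolverError("non-finite displacement solution (rank-deficient?)")
        return u, K


def solve(
    mesh: Mesh,
    materials: Mapping[str, Material],
    bcs: BoundaryConditions,
    loads: "np.ndarray | object",
    thickness: float = DEFAULT_THICKNESS,
    moduli: Mapping[str, float] | None = None,
) -> DisplacementField:
    """Static solve: assemble, constrain, factorise, check equilibrium.

    ``loads`` is either a flat (2N,) nodal force vector or an object with a
    ``nodal_forces(mesh)`` method (a :class:`whaleram.loading.LoadCase`).
    """
    f = loads if isinstance(loads, np.ndarray) else loads.nodal_forces(mesh)
    t0 = time.perf_counter()
    decomp = StiffnessDecomposition(mesh, materials, thickness=thickness)
    system = LinearSystem(decomp, bcs)
    u, K = system.solve(f, moduli)
    residual = K @ u - f
    total_applied = np.abs(f).sum()
    imbalance = np.abs(residual[system.free]).max() if system.free.any() else 0.0
    rel = imbalance / max(total_applied, 1e-30)
    log.info(
        "solve: %d nodes, %d elements, free-dof residual %.2e (rel %.2e), %.3f s",
        mesh.n_nodes, mesh.n_elements, imbalance, rel, time.perf_counter() - t0,
    )
    return DisplacementField(u=u.reshape(-1, 2))


def recover_stresses(
    mesh: Mesh,
    displacement: DisplacementField,
    materials: Mapping[str, Material],
    moduli_per_element: np.ndarray | None = None,
) -> StressField:
    """Element-wise constant stress sigma = D B u_e.

    ``moduli_per_element`` optionally overrides the Young's modulus per
    element (Monte Carlo sampling); Poisson ratios always come from
    ``materials``.
    """
    B, _ = _b_matrices(mesh)
    u = displacement.u
    ue = u[mesh.triangles].reshape(mesh.n_elements, 6)
    strain = np.einsum("eij,ej->ei", B, ue)
    stress = np.empty_like(strain)
    for lab in np.unique(mesh.element_material):
        sel = mesh.element_material == lab
        mat = materials[lab]
        D = mat.d_matrix()
        s = strain[sel] @ D.T
        if moduli_per_element is not None:
            s *= (moduli_per_element[sel] / mat.E)[:, None]
        stress[sel] = s
    return StressField(sxx=stress[:, 0], syy=stress[:, 1], txy=stress[:, 2])


def reaction_forces(
    mesh: Mesh,
    displacement: DisplacementField,
    materials: Mapping[str, Material],
    bcs: BoundaryConditions,
    f_ext: np.ndarray | None = None,
    thickness: float = DEFAULT_THICKNESS,
    moduli: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Total (F_x, F_y) reaction at the fixed nodes, in N.

    Computed as K u - f_ext restricted to the constrained dofs; by global
    equilibrium this equals minus the total applied load.
    """
    decomp = StiffnessDecomposition(mesh, materials, thickness=thickness)
    K = decomp.matrix(moduli)
    r = K @ displacement.flat()
    if f_ext is not None:
        r = r - f_ext
    fixed_dofs, _ = bcs.dof_values(mesh.n_nodes)
    rx = r[fixed_dofs[0::2]].sum()
    ry = r[fixed_dofs[1::2]].sum()
    return np.array([rx, ry])
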