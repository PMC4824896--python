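"""Quasi-static ramming load cases.

The impact is modelled as a steady force obtained from collision kinematics,
F = m v^2 / (2 d): the whale's kinetic energy divided by the deceleration
distance (the junk overhang beyond the skull tip).  With the defaults
(39,000 kg at 6.26 m/s stopping over 1 m) this gives 764 kN.

The force is distributed as a uniform traction over a labelled anterior
boundary segment: the spermaceti organ face, the full anterior junk face, or
its superior/middle/inferior thirds.  Angle 0 is the posteriorly directed
(caudal, +x) horizontal — the head is compressed front-to-back; positive
angles tilt the load ventrally (toward -y), collinear with the anterior
partition at the 20.56 degree variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Mesh


@dataclass(frozen=True)
class ImpactParams:
    """Collision kinematics: mass (kg), speed (m/s), stopping distance (m)."""

    mass: float = 39_000.0
    speed: float = 6.26
    decel_distance: float = 1.0

    def __post_init__(self):
        if not self.mass > 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")
        if self.speed < 0:
            raise ValueError(f"speed must be >= 0, got {self.speed}")
        if not self.decel_distance > 0:
            raise ValueError(
                f"decel_distance must be > 0, got {self.decel_distance}"
            )


def impact_force(params: ImpactParams = ImpactParams()) -> float:
    """Quasi-static ramming force in N: F = m v^2 / (2 d)."""
    return params.mass * params.speed**2 / (2 * params.decel_distance)


#: load-site label -> anterior boundary segment labels
SITES: dict[str, tuple[str, ...]] = {
    "organ": ("anterior_organ",),
    "junk_superior": ("anterior_junk_superior",),
    "junk_mid": ("anterior_junk_mid",),
    "junk_inferior": ("anterior_junk_inferior",),
    "junk_full": (
        "anterior_junk_superior",
        "anterior_junk_mid",
        "anterior_junk_inferior",
    ),
}


@dataclass(frozen=True)
class LoadCase:
    """Uniform traction over a labelled anterior segment.

    ``traction`` is the force per metre of boundary length (N/m, slab
    thickness folded in) along ``direction``; the traction integral over the
    loaded edges reproduces ``total_force`` exactly.
    """

    site: str
    angle_deg: float
    total_force: float
    edges: np.ndarray       # (M, 2) node pairs
    edge_lengths: np.ndarray
    direction: np.ndarray   # unit vector

    @property
    def traction(self) -> float:
        return self.total_force / float(self.edge_lengths.sum())

    def total_vector(self) -> np.ndarray:
        """Applied (F_x, F_y) in N."""
        return self.total_force * self.direction

    def nodal_forces(self, mesh: Mesh) -> np.ndarray:
        """Consistent nodal load vector (2N,): each edge splits its share
        of the traction equally between its two end nodes."""
        f = np.zeros(2 * mesh.n_nodes)
        t = self.traction
        for (a, b), length in zip(self.edges, self.edge_lengths):
            fe = 0.5 * t * length * self.direction
            f[2 * a : 2 * a + 2] += fe
            f[2 * b : 2 * b + 2] += fe
        return f


def load_direction(angle_deg: float) -> np.ndarray:
    """Unit load direction: angle 0 is caudal (+x); positive tilts ventrally."""
    th = math.radians(angle_deg)
    return np.array([math.cos(th), -math.sin(th)])


def make_load_case(
    mesh: Mesh,
    site: str,
    angle_deg: float = 0.0,
    total_force: float | None = None,
    impact: ImpactParams | None = None,
) -> LoadCase:
    """Build a uniform-traction load case on a labelled anterior segment.

    ``total_force`` in N, or ``impact`` kinematics from which it is derived;
    defaults to the nominal 764 kN ramming force.
    """
    if site not in SITES:
        raise ValueError(
            f"unknown load site {site!r}; valid sites: {sorted(SITES)}"
        )
    if total_force is None:
        total_force = impact_force(impact or ImpactParams())
    edges = mesh.edges_with_label(SITES[site])
    if len(edges) == 0:
        raise ValueError(f"mesh has no boundary edges for site {site!r}")
    d = mesh.nodes[edges[:, 1]] - mesh.nodes[edges[:, 0]]
    lengths = np.hypot(d[:, 0], d[:, 1])
    return LoadCase(
        site=site,
        angle_deg=float(angle_deg),
        total_force=float(total_force),
        edges=edges,
        edge_lengths=lengths,
        direction=load_direction(angle_deg),
    )
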