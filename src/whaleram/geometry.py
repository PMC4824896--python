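"""Parametric 2D profile of the sperm whale forehead and its triangulation.

The forehead is idealised as a 0.1 m-thick sagittal slab, 5.3 m long and
1.6 m high, built from five labelled tissue regions:

* ``skull``      — the upper jaw below the soft tissues, whose dorsal surface
                   forms a shallow trough cradling the junk, plus the cranial
                   wall filling the posterior end of the domain;
* ``case``       — the fibrous connective-tissue case enclosing the junk
                   (dorsal and ventral walls);
* ``junk_oil``   — the oil/wax compartments of the junk;
* ``partition``  — the near-vertical connective-tissue partitions dividing the
                   junk, trapezoidal (narrow ventrally, broad dorsally);
* ``organ``      — the spermaceti organ riding on top of the junk.

Model variants: ``A`` has twelve 0.05 m partitions separated by 0.150 m oil
compartments, ``A2`` is A with a monotone anterior-to-posterior thickness
taper, ``B`` has six partitions over the same partitioned span, ``C`` has
none.  All region boundaries are piecewise linear, so the profile tiles the
bounding rectangle exactly and the mapped block-grid mesher below produces a
conforming triangulation whose elements inherit region labels exactly.

Coordinates: x in metres increasing caudally from the anterior tip (x = 0),
y increasing dorsally from the ventral skull margin (y = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

REGION_LABELS = ("case", "junk_oil", "organ", "partition", "skull")

#: boundary segment labels used for loading / constraints
SEGMENT_LABELS = (
    "anterior_organ",
    "anterior_junk_superior",
    "anterior_junk_mid",
    "anterior_junk_inferior",
    "posterior",
    "other",
)

VARIANTS = ("A", "A2", "B", "C")


class GeometryError(ValueError):
    """Raised when parameters describe an infeasible head profile."""


@dataclass(frozen=True)
class HeadGeometryParams:
    """Dimensions of the parametric head profile (all lengths in metres)."""

    overall_length: float = 5.3
    overall_height: float = 1.6
    slab_thickness: float = 0.1
    organ_length: float = 5.0
    n_partitions: int = 12
    #: uniform thickness, or one value per partition (Model A2)
    partition_thickness: float | tuple[float, ...] = 0.05
    compartment_spacing: float = 0.150
    skull_base_thickness: float = 0.35
    #: trough depth at mid-rostrum as a fraction of skull_base_thickness
    skull_trough_depth_fraction: float = 0.30
    case_thickness: float = 0.05
    organ_thickness: float = 0.60
    #: dorsal/ventral width ratio of the trapezoidal partitions
    partition_taper_ratio: float = 1.5

    def thicknesses(self) -> tuple[float, ...]:
        t = self.partition_thickness
        if isinstance(t, (int, float)):
            return (float(t),) * self.n_partitions
        t = tuple(float(v) for v in t)
        if len(t) != self.n_partitions:
            raise GeometryError(
                f"{len(t)} partition thicknesses given for "
                f"{self.n_partitions} partitions"
            )
        return t

    def validate(self) -> None:
        pos = {
            "overall_length": self.overall_length,
            "overall_height": self.overall_height,
            "slab_thickness": self.slab_thickness,
            "organ_length": self.organ_length,
            "skull_base_thickness": self.skull_base_thickness,
            "case_thickness": self.case_thickness,
            "organ_thickness": self.organ_thickness,
        }
        for name, v in pos.items():
            if not v > 0:
                raise GeometryError(f"{name} must be > 0, got {v}")
        if self.n_partitions < 0:
            raise GeometryError("n_partitions must be >= 0")
        if self.organ_length > self.overall_length:
            raise GeometryError("organ_length exceeds overall_length")
        if not 0 <= self.skull_trough_depth_fraction < 1:
            raise GeometryError("skull_trough_depth_fraction must be in [0, 1)")
        if self.partition_taper_ratio < 1:
            raise GeometryError("partition_taper_ratio must be >= 1")
        if self.n_partitions:
            ts = self.thicknesses()
            if any(t <= 0 for t in ts):
                raise GeometryError("partition thicknesses must be > 0")
            if self.compartment_spacing <= 0:
                raise GeometryError("compartment_spacing must be > 0")
            zone = sum(ts) + self.n_partitions * self.compartment_spacing
            if zone > self.organ_length + 1e-12:
                raise GeometryError(
                    f"partitions and compartments span {zone:.3f} m but the "
                    f"junk is only {self.organ_length:.3f} m long"
                )
        soft = (
            self.skull_base_thickness
            + 2 * self.case_thickness
            + self.organ_thickness
        )
        if soft >= self.overall_height:
            raise GeometryError(
                "skull + case walls + organ leave no room for the junk"
            )


def params_for_variant(variant: str, **overrides) -> HeadGeometryParams:
    """Preset parameters for the four model variants.

    ``A``: 12 uniform 0.05 m partitions at 0.150 m spacing.
    ``A2``: as A but with a linear 0.08 -> 0.02 m anterior-to-posterior taper
    (mean 0.05 m), emulating the progressive posterior thinning of the real
    partitions.  ``B``: 6 partitions over the same 2.4 m partitioned span.
    ``C``: no partitions.
    """
    if variant == "A":
        base = dict(n_partitions=12, partition_thickness=0.05,
                    compartment_spacing=0.150)
    elif variant == "A2":
        taper = tuple(np.linspace(0.08, 0.02, 12))
        base = dict(n_partitions=12, partition_thickness=taper,
                    compartment_spacing=0.150)
    elif variant == "B":
        # same 12*(0.05+0.150) = 2.4 m partitioned span, six partitions
        base = dict(n_partitions=6, partition_thickness=0.05,
                    compartment_spacing=(2.4 - 6 * 0.05) / 6)
    elif variant == "C":
        base = dict(n_partitions=0)
    else:
        raise GeometryError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    base.update(overrides)
    return HeadGeometryParams(**base)


# ---------------------------------------------------------------------------
# grid plan: the structured description the mesher consumes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _GridPlan:
    """Mapped block-grid layout of a geometry.

    ``lines`` are the mandatory grid lines, each a (x_bottom, x_top) pair —
    lines may tilt across the junk band to follow the trapezoidal partition
    walls and are vertical elsewhere.  ``interfaces`` are the horizontal layer
    boundaries as piecewise-linear functions of x (bottom-up), delimiting
    ``blocks``.  Region labels are exact functions of (column, block).
    """

    lines: tuple[tuple[float, float], ...]
    col_labels: tuple[str, ...]          # junk-band label per column interval
    interface_x: tuple[float, ...]       # shared breakpoints of interfaces
    interface_y: tuple[tuple[float, ...], ...]  # y values per interface
    blocks: tuple[str, ...]              # label per layer, bottom-up
    junk_block: int | None               # index into blocks, or None
    organ_length: float | None           # columns beyond it are all skull
    kind: str                            # "head" | "rect"

    def interface(self, k: int, x) -> np.ndarray:
        return np.interp(x, self.interface_x, self.interface_y[k])


@dataclass(frozen=True)
class HeadGeometry:
    """Labelled polygonal tiling of the head profile.

    ``regions`` is a list of ``(polygon, label)`` pairs; polygons are (N, 2)
    CCW vertex arrays that tile the bounding rectangle exactly.
    """

    regions: tuple[tuple[np.ndarray, str], ...]
    params: HeadGeometryParams
    variant: str
    plan: _GridPlan = field(repr=False)

    @property
    def bounding_box(self) -> tuple[float, float]:
        return self.params.overall_length, self.params.overall_height

    def total_area(self) -> float:
        return float(sum(polygon_area(p) for p, _ in self.regions))

    def region_areas(self) -> dict[str, float]:
        areas: dict[str, float] = {}
        for poly, label in self.regions:
            areas[label] = areas.get(label, 0.0) + polygon_area(poly)
        return areas

    def n_partitions(self) -> int:
        return sum(1 for _, label in self.regions if label == "partition")


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a simple polygon (positive if CCW)."""
    x, y = np.asarray(poly, float).T
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _partition_walls(params: HeadGeometryParams) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Left/right wall lines ((xb, xt) pairs) of each partition.

    Partitions are symmetric trapezoids widening dorsally with mean thickness
    equal to the nominal one.  The anterior-most partition sits one oil
    compartment behind the anterior junk face: the rammed face itself is oil
    backed by the case, so the partitions are loaded through the oil (in
    tension as the compressed oil displaces dorsoventrally) rather than
    taking the impact head-on.
    """
    ts = params.thicknesses()
    r = params.partition_taper_ratio
    walls = []
    x = params.compartment_spacing
    for t in ts:
        delta = t * (r - 1) / (2 * (r + 1))  # (w_top - t) / 2
        c = x + t / 2
        left = (c - t / 2 + delta, c - t / 2 - delta)
        right = (c + t / 2 - delta, c + t / 2 + delta)
        walls.append((left, right))
        x += t + params.compartment_spacing
    return walls


def build_head_profile(
    params: HeadGeometryParams | None = None,
    variant: str = "A",
    **overrides,
) -> HeadGeometry:
    """Construct the labelled polygonal head profile for a model variant.

    Variant ``A``/``A2`` must carry 12 partitions, ``B`` six and ``C`` none;
    explicit ``params`` are checked for consistency with ``variant``.
    """
    if params is None:
        params = params_for_variant(variant, **overrides)
    elif overrides:
        params = replace(params, **overrides)
    params.validate()

    expected = {"A": 12, "A2": 12, "B": 6, "C": 0}
    if variant not in expected:
        raise GeometryError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if params.n_partitions != expected[variant]:
        raise GeometryError(
            f"variant {variant} requires {expected[variant]} partitions, "
            f"params give {params.n_partitions}"
        )
    if variant == "A2" and isinstance(params.partition_thickness, (int, float)):
        raise GeometryError("variant A2 requires a per-partition thickness list")

    L, H = params.overall_length, params.overall_height
    Lo = params.organ_length
    s0 = params.skull_base_thickness
    tc = params.case_thickness
    trough = params.skull_trough_depth_fraction * s0
    y_organ = H - params.organ_thickness
    y_case_hi = y_organ - tc

    # piecewise-linear layer interfaces, shared x breakpoints
    ix = (0.0, Lo / 2, Lo, L)
    y_skull = (s0, s0 - trough, s0, s0)
    y_case_lo = tuple(v + tc for v in y_skull)
    if max(y_case_lo) >= y_case_hi:
        raise GeometryError("case walls meet: junk band has no thickness")
    interface_y = (
        (0.0,) * 4,
        y_skull,
        y_case_lo,
        (y_case_hi,) * 4,
        (y_organ,) * 4,
        (H,) * 4,
    )
    blocks = ("skull", "case", "junk", "case", "organ")

    def f_skull(x):
        return np.interp(x, ix, y_skull)

    def f_case_lo(x):
        return np.interp(x, ix, y_case_lo)

    # mandatory grid lines through the junk band
    walls = _partition_walls(params)
    lines: list[tuple[float, float]] = [(0.0, 0.0)]
    col_labels: list[str] = []
    for left, right in walls:
        lines.append(left)
        col_labels.append("junk_oil")
        lines.append(right)
        col_labels.append("partition")
    lines.append((Lo, Lo))
    col_labels.append("junk_oil")
    lines.append((L, L))
    col_labels.append("skull")  # posterior cranium block

    # interface breakpoints (the trough vertex) must be grid lines so the
    # mesh follows every region boundary exactly
    for bp in ix[1:-1]:
        for i in range(len(lines) - 1):
            if lines[i][0] < bp < lines[i + 1][0] and lines[i][1] < bp < lines[i + 1][1]:
                lines.insert(i + 1, (bp, bp))
                col_labels.insert(i + 1, col_labels[i])
                break

    xs_b = [l[0] for l in lines]
    xs_t = [l[1] for l in lines]
    if any(b >= a for a, b in zip(xs_b[1:], xs_b)) or any(
        b >= a for a, b in zip(xs_t[1:], xs_t)
    ):
        raise GeometryError("partition walls cross or do not fit within the junk")

    plan = _GridPlan(
        lines=tuple(lines),
        col_labels=tuple(col_labels),
        interface_x=ix,
        interface_y=interface_y,
        blocks=blocks,
        junk_block=2,
        organ_length=Lo,
        kind="head",
    )

    # ---------------- region polygons ----------------
    def lower_polyline(x0, x1, f):
        """Vertices along a piecewise-linear interface from x0 to x1."""
        xs = [x0] + [b for b in ix if x0 < b < x1] + [x1]
        return [(x, float(f(np.asarray(x)))) for x in xs]

    regions: list[tuple[np.ndarray, str]] = []

    # skull: ventral band under the soft tissues + posterior cranial wall
    skull = [(0.0, 0.0), (L, 0.0), (L, H), (Lo, H), (Lo, float(f_skull(Lo)))]
    skull += list(reversed(lower_polyline(0.0, Lo, f_skull)))[1:]
    regions.append((np.array(skull[:-1] if skull[-1] == skull[0] else skull), "skull"))

    # ventral case wall
    lo = lower_polyline(0.0, Lo, f_skull)
    hi = lower_polyline(0.0, Lo, f_case_lo)
    regions.append((np.array(lo + list(reversed(hi))), "case"))

    # junk band: partitions and oil compartments between the wall lines
    for (xb0, xt0), (xb1, xt1), lab in zip(lines[:-2], lines[1:-1], col_labels[:-1]):
        bottom = lower_polyline(xb0, xb1, f_case_lo)
        poly = bottom + [(xt1, y_case_hi), (xt0, y_case_hi)]
        regions.append((np.array(poly), lab))

    # dorsal case wall and organ
    regions.append((
        np.array([(0.0, y_case_hi), (Lo, y_case_hi), (Lo, y_organ), (0.0, y_organ)]),
        "case",
    ))
    regions.append((
        np.array([(0.0, y_organ), (Lo, y_organ), (Lo, H), (0.0, H)]),
        "organ",
    ))

    geom = HeadGeometry(
        regions=tuple(regions), params=params, variant=variant, plan=plan
    )
    assert abs(geom.total_area() - L * H) < 1e-9 * L * H
    return geom


def rectangle_geometry(
    width: float, height: float, label: str = "plate"
) -> HeadGeometry:
    """Single-region rectangular geometry (used for solver verification)."""
    if width <= 0 or height <= 0:
        raise GeometryError("rectangle dimensions must be > 0")
    params = HeadGeometryParams(
        overall_length=width, overall_height=height, organ_length=width,
        n_partitions=0, skull_base_thickness=height / 4,
        case_thickness=height / 8, organ_thickness=height / 4,
        skull_trough_depth_fraction=0.0,
    )
    plan = _GridPlan(
        lines=((0.0, 0.0), (width, width)),
        col_labels=(label,),
        interface_x=(0.0, width),
        interface_y=((0.0, 0.0), (height, height)),
        blocks=(label,),
        junk_block=None,
        organ_length=None,
        kind="rect",
    )
    poly = np.array([(0.0, 0.0), (width, 0.0), (width, height), (0.0, height)])
    return HeadGeometry(
        regions=((poly, label),), params=params, variant="C", plan=plan
    )


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mesh:
    """Conforming triangulation with per-element region labels.

    nodes: (N, 2) coordinates in metres; triangles: (E, 3) CCW node triples;
    element_material: (E,) region label per element; boundary_edges: (B, 2)
    node pairs on the domain boundary with boundary_labels: (B,) segment
    labels.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    element_material: np.ndarray
    boundary_edges: np.ndarray
    boundary_labels: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_coords(self) -> np.ndarray:
        """(E, 3, 2) vertex coordinates per element."""
        return self.nodes[self.triangles]

    def element_areas(self) -> np.ndarray:
        c = self.element_coords()
        v1 = c[:, 1] - c[:, 0]
        v2 = c[:, 2] - c[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def element_centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def edges_with_label(self, labels: str | Sequence[str]) -> np.ndarray:
        if isinstance(labels, str):
            labels = (labels,)
        mask = np.isin(self.boundary_labels, list(labels))
        return self.boundary_edges[mask]

    def nodes_on_segment(self, labels: str | Sequence[str]) -> np.ndarray:
        return np.unique(self.edges_with_label(labels))


def _subdivide(a: float, b: float, n: int) -> list[float]:
    return [a + (b - a) * i / n for i in range(1, n)]


def generate_mesh(geometry: HeadGeometry, target_h: float) -> Mesh:
    """Triangulate a geometry with nominal element size ``target_h``.

    Every layer block and every column interval gets at least one element
    through its thickness (local refinement of thin partitions and case walls
    is automatic), cell extents never exceed ``target_h``, and element labels
    are exact: each cell lies wholly inside one region by construction.
    Deterministic: identical inputs give bit-identical meshes.
    """
    if not target_h > 0:
        raise GeometryError(f"target_h must be > 0, got {target_h}")
    plan = geometry.plan
    h = float(target_h)

    # --- columns: mandatory lines plus even subdivision to <= h ---
    lines: list[tuple[float, float]] = []
    col_labels: list[str] = []
    for (l0, l1), lab in zip(
        zip(plan.lines[:-1], plan.lines[1:]), plan.col_labels
    ):
        span = max(l1[0] - l0[0], l1[1] - l0[1])
        nsub = max(1, math.ceil(span / h - 1e-9))
        lines.append(l0)
        for xb, xt in zip(
            _subdivide(l0[0], l1[0], nsub), _subdivide(l0[1], l1[1], nsub)
        ):
            lines.append((xb, xt))
        col_labels.extend([lab] * nsub)
    lines.append(plan.lines[-1])
    xb = np.array([l[0] for l in lines])
    xt = np.array([l[1] for l in lines])

    # --- rows: per block, enough to keep cell height <= h everywhere ---
    nblocks = len(plan.blocks)
    block_rows: list[int] = []
    for k in range(nblocks):
        th = plan.interface(k + 1, xb) - plan.interface(k, xb)
        if np.any(th <= 0):
            raise GeometryError(f"block {plan.blocks[k]!r} has non-positive thickness")
        block_rows.append(max(1, math.ceil(float(th.max()) / h - 1e-9)))
    row_block = np.concatenate(
        [np.full(n, k, dtype=int) for k, n in enumerate(block_rows)]
    )
    total_rows = int(row_block.size)

    # --- nodes ---
    ncols = len(lines)
    nodes = np.empty(((total_rows + 1) * ncols, 2))
    jb = plan.junk_block
    # row index at junk band bottom/top, for the tilt interpolation
    if jb is not None:
        j_lo = int(np.sum([block_rows[k] for k in range(jb)]))
        j_hi = j_lo + block_rows[jb]
    for i in range(ncols):
        levels = [float(plan.interface(k, xb[i])) for k in range(nblocks + 1)]
        j = 0
        ys = []
        for k in range(nblocks):
            n = block_rows[k]
            for r in range(n):
                ys.append(levels[k] + (levels[k + 1] - levels[k]) * r / n)
            j += n
        ys.append(levels[-1])
        for j, y in enumerate(ys):
            if jb is None or j <= j_lo:
                x = xb[i]
            elif j >= j_hi:
                x = xt[i]
            else:
                f = (j - j_lo) / (j_hi - j_lo)
                x = xb[i] + f * (xt[i] - xb[i])
            nodes[j * ncols + i] = (x, y)

    def nid(i: int, j: int) -> int:
        return j * ncols + i

    # --- triangles: parity-alternating quad split ---
    tris = []
    mats = []
    col_mid_b = 0.5 * (xb[:-1] + xb[1:])
    for j in range(total_rows):
        blk = plan.blocks[row_block[j]]
        for i in range(ncols - 1):
            if plan.kind == "head" and col_mid_b[i] >= plan.organ_length:
                lab = "skull"
            elif plan.junk_block is not None and row_block[j] == plan.junk_block:
                lab = col_labels[i]
            elif plan.kind == "rect":
                lab = plan.blocks[0]
            else:
                lab = blk
            n00, n10 = nid(i, j), nid(i + 1, j)
            n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
            if (i + j) % 2 == 0:
                tris += [(n00, n10, n11), (n00, n11, n01)]
            else:
                tris += [(n00, n10, n01), (n10, n11, n01)]
            mats += [lab, lab]
    triangles = np.array(tris, dtype=np.int64)
    materials = np.array(mats)

    # --- boundary edges ---
    edges = []
    labels = []
    if plan.kind == "head":
        y_junk_lo = float(plan.interface(jb, 0.0))
        y_junk_hi = float(plan.interface(jb + 1, 0.0))
        third = (y_junk_hi - y_junk_lo) / 3
        junk_thirds = (
            "anterior_junk_inferior",
            "anterior_junk_mid",
            "anterior_junk_superior",
        )
    for j in range(total_rows):
        # left boundary (anterior face, x = 0)
        n0, n1 = nid(0, j), nid(0, j + 1)
        if plan.kind == "head":
            blk = plan.blocks[row_block[j]]
            if blk == "organ":
                lab = "anterior_organ"
            elif row_block[j] == jb:
                ym = 0.5 * (nodes[n0, 1] + nodes[n1, 1])
                k = min(2, int((ym - y_junk_lo) / third))
                lab = junk_thirds[k]
            else:
                lab = "other"
        else:
            lab = "left"
        edges.append((n0, n1))
        labels.append(lab)
        # right boundary (posterior face, x = overall_length)
        edges.append((nid(ncols - 1, j), nid(ncols - 1, j + 1)))
        labels.append("posterior" if plan.kind == "head" else "right")
    for i in range(ncols - 1):
        edges.append((nid(i, 0), nid(i + 1, 0)))
        labels.append("other" if plan.kind == "head" else "bottom")
        edges.append((nid(i, total_rows), nid(i + 1, total_rows)))
        labels.append("other" if plan.kind == "head" else "top")

    mesh = Mesh(
        nodes=nodes,
        triangles=triangles,
        element_material=materials,
        boundary_edges=np.array(edges, dtype=np.int64),
        boundary_labels=np.array(labels),
    )
    areas = mesh.element_areas()
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise GeometryError(f"degenerate element {bad} (area {areas[bad]:.3e})")
    total = geometry.total_area()
    if abs(areas.sum() - total) > 1e-9 * total:
        raise GeometryError("mesh does not tile the geometry")
    return mesh


def partition_components(mesh: Mesh) -> list[np.ndarray]:
    """Element-index arrays of the connected partition components.

    Components are computed by edge adjacency among elements labelled
    ``partition`` and returned sorted by anterior-to-posterior centroid x.
    """
    idx = np.flatnonzero(mesh.element_material == "partition")
    if idx.size == 0:
        return []
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    tri = mesh.triangles[idx]
    edge_map: dict[tuple[int, int], int] = {}
    rows, cols = [], []
    for e, t in enumerate(tri):
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            key = (a, b) if a < b else (b, a)
            if key in edge_map:
                rows.append(edge_map[key])
                cols.append(e)
            else:
                edge_map[key] = e
    n = len(idx)
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    ncomp, comp = connected_components(adj, directed=False)
    cents = mesh.element_centroids()[idx, 0]
    groups = [idx[comp == c] for c in range(ncomp)]
    groups.sort(key=lambda g: float(cents[np.searchsorted(idx, g)].mean()))
    return groups
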