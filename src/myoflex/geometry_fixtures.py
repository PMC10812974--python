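"""Synthetic meshes and mesh file I/O.

All meshes are structured tetrahedral grids built from hexahedral cells split
with the Kuhn (Freudenthal) six-tetrahedron template, which is conforming
across neighbouring cells when the template's corner bits follow the global
x/y/z index directions — including across the tendon-bone weld, where the
distal tendon's square end face reuses a patch of the bone's top-surface
nodes verbatim.

The idealised forearm consists of

* a slender prismatic radius (bone) of square cross-section along +X, pinned
  at its proximal end (the elbow hinge),
* a fusiform biceps (muscle) hanging vertically above the insertion point
  with a sinusoidal radius profile and squircle-mapped circular sections, and
* two tendon straps: a proximal strap whose free top face is fully fixed
  (standing in for the humeral attachment) and a distal strap that morphs
  from the circular muscle section to the bone's square section and shares
  its end nodes with the bone (the insertion).

Axes: X distal along the radius, Z vertical (the load acts in -Z),
Y mediolateral.  Units mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fem_core import Mesh

__all__ = [
    "ForearmGeometryParams",
    "MeshIOError",
    "make_unit_fixture",
    "make_cylinder",
    "make_synthetic_forearm",
    "generative_region_volumes",
    "region_volumes",
    "min_dihedral_angle",
    "read_mesh",
    "write_mesh",
]

# Kuhn paths (axis bit order x=1, y=2, z=4); conforming across cells.
_KUHN = np.array(
    [[0, 1, 3, 7], [0, 1, 5, 7], [0, 2, 3, 7],
     [0, 2, 6, 7], [0, 4, 5, 7], [0, 4, 6, 7]]
)


class MeshIOError(ValueError):
    pass


def _kuhn_split(corners: np.ndarray) -> np.ndarray:
    """Split hexes (n, 8) given in corner-bit order into tets (n*6, 4)."""
    return corners[:, _KUHN].reshape(-1, 4)


def _fix_orientation(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    x = points[cells]
    v = np.linalg.det(x[:, 1:] - x[:, :1])
    cells = cells.copy()
    neg = v < 0.0
    cells[neg, 2], cells[neg, 3] = cells[neg, 3].copy(), cells[neg, 2].copy()
    return cells


def _grid_hexes(ids: np.ndarray) -> np.ndarray:
    """Hex corner array from a node-id grid (nx, ny, nz), bits (x, y, z)."""
    c = np.empty(tuple(np.array(ids.shape) - 1) + (8,), dtype=np.int64)
    for code in range(8):
        dx, dy, dz = code & 1, (code >> 1) & 1, (code >> 2) & 1
        c[..., code] = ids[dx: ids.shape[0] - 1 + dx,
                           dy: ids.shape[1] - 1 + dy,
                           dz: ids.shape[2] - 1 + dz]
    return c.reshape(-1, 8)


# ---------------------------------------------------------------------------
# Unit fixtures
# ---------------------------------------------------------------------------

def make_unit_fixture(kind: str, subdivisions: int = 1, region: str = "muscle") -> Mesh:
    """Validation fixture: a single tetrahedron or a subdivided unit cube.

    Face node sets are named x0, x1, y0, y1, z0, z1 (nodes on the respective
    coordinate plane).  The cube uses ``6 * subdivisions**3`` tetrahedra and
    conserves the unit volume exactly.
    """
    if subdivisions < 1:
        raise ValueError("subdivisions must be >= 1")
    if kind == "single_tet":
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        cells = np.array([[0, 1, 2, 3]])
    elif kind == "unit_cube":
        n = subdivisions + 1
        xs = np.linspace(0.0, 1.0, n)
        ids = np.arange(n**3).reshape(n, n, n)
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        cells = _kuhn_split(_grid_hexes(ids))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    cells = _fix_orientation(pts, cells)
    sets = {}
    for axis, name in ((0, "x"), (1, "y"), (2, "z")):
        sets[f"{name}0"] = np.nonzero(np.abs(pts[:, axis]) < 1e-12)[0]
        sets[f"{name}1"] = np.nonzero(np.abs(pts[:, axis] - 1.0) < 1e-12)[0]
    mesh = Mesh(pts, cells, np.full(len(cells), region), sets)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Structured tubes
# ---------------------------------------------------------------------------

def _squircle(n: int) -> np.ndarray:
    """Unit-disk mapping of the [-1,1]^2 grid; (n*n, 2), index (i, j) = (x, y)."""
    u = np.linspace(-1.0, 1.0, n)
    U, V = np.meshgrid(u, u, indexing="ij")
    X = U * np.sqrt(1.0 - 0.5 * V**2)
    Y = V * np.sqrt(1.0 - 0.5 * U**2)
    return np.stack([X.ravel(), Y.ravel()], axis=1)


def _square(n: int) -> np.ndarray:
    u = np.linspace(-1.0, 1.0, n)
    U, V = np.meshgrid(u, u, indexing="ij")
    return np.stack([U.ravel(), V.ravel()], axis=1)


def make_cylinder(length: float, radius: float, n_axial: int, n_cross: int = 5,
                  region: str = "muscle") -> Mesh:
    """Straight circular cylinder along +Z with end sets ``end0`` / ``end1``."""
    disk = _squircle(n_cross) * radius
    zs = np.linspace(0.0, length, n_axial + 1)
    npts = n_cross * n_cross
    pts = np.empty((len(zs) * npts, 3))
    for k, z in enumerate(zs):
        pts[k * npts:(k + 1) * npts, :2] = disk
        pts[k * npts:(k + 1) * npts, 2] = z
    ids = (
        np.arange(len(zs) * npts)
        .reshape(len(zs), n_cross, n_cross)
        .transpose(1, 2, 0)
    )
    cells = _fix_orientation(pts, _kuhn_split(_grid_hexes(ids)))
    sets = {
        "end0": np.arange(npts),
        "end1": np.arange((len(zs) - 1) * npts, len(zs) * npts),
    }
    mesh = Mesh(pts, cells, np.full(len(cells), region), sets)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Synthetic forearm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForearmGeometryParams:
    """Generation parameters of the idealised forearm (mm).

    ``radius_radius`` is the half-width of the square bone section and also
    the half-side of the distal tendon's welded end face.  ``edge_length`` is
    the target axial spacing; ``n_cross`` (odd) the nodes across a section.
    ``jitter`` optionally perturbs strictly interior nodes (seeded) to break
    the structured-mesh symmetry.
    """

    radius_length: float = 250.0
    radius_radius: float = 5.0
    muscle_length: float = 240.0
    muscle_max_radius: float = 31.0
    tendon_length: float = 30.0
    tendon_radius: float = 24.0
    insertion_fraction: float = 0.25
    #: fraction of the fusiform body at each end labelled tendon
    #: (aponeurosis / myotendinous junction); the contractile muscle region
    #: is the belly between the two junctions
    aponeurosis_fraction: float = 0.15
    edge_length: float = 18.0
    n_cross: int = 5
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        for name in ("radius_length", "radius_radius", "muscle_length",
                     "muscle_max_radius", "tendon_length", "tendon_radius",
                     "edge_length"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.muscle_length >= self.radius_length + self.tendon_length:
            raise ValueError("muscle_length too large for the radius span")
        if self.n_cross < 3 or self.n_cross % 2 == 0:
            raise ValueError("n_cross must be odd and >= 3")

    def scaled(self, factor: float) -> "ForearmGeometryParams":
        """All lengths scaled by ``factor`` (same discretization density)."""
        return ForearmGeometryParams(
            radius_length=self.radius_length * factor,
            radius_radius=self.radius_radius * factor,
            muscle_length=self.muscle_length * factor,
            muscle_max_radius=self.muscle_max_radius * factor,
            tendon_length=self.tendon_length * factor,
            tendon_radius=self.tendon_radius * factor,
            insertion_fraction=self.insertion_fraction,
            aponeurosis_fraction=self.aponeurosis_fraction,
            edge_length=self.edge_length * factor,
            n_cross=self.n_cross,
            seed=self.seed,
            jitter=self.jitter * factor,
        )


def _chain_section(p: ForearmGeometryParams, z: float, z0: float):
    """Section offsets (n^2, 2) of the tendon-muscle-tendon chain at height z."""
    nc = p.n_cross
    a = p.radius_radius
    z1 = z0 + p.tendon_length
    z2 = z1 + p.muscle_length
    z3 = z2 + p.tendon_length
    disk = _squircle(nc)
    if z <= z1:  # distal strap: square (weld) -> circle
        w = (z - z0) / p.tendon_length
        return (1.0 - w) * _square(nc) * a + w * disk * p.tendon_radius
    if z <= z2:  # fusiform muscle
        t = (z - z1) / p.muscle_length
        r = p.tendon_radius + (p.muscle_max_radius - p.tendon_radius) * np.sin(
            np.pi * t
        )
        return disk * r
    if z <= z3 + 1e-9:  # proximal strap
        return disk * p.tendon_radius
    raise ValueError("height outside the chain")


def _bone_stations(p: ForearmGeometryParams):
    """Bone axial stations with one station exactly at the insertion line."""
    x_ins = p.insertion_fraction * p.radius_length
    n1 = max(2, int(round(x_ins / p.edge_length)))
    n2 = max(2, int(round((p.radius_length - x_ins) / p.edge_length)))
    left = np.linspace(0.0, x_ins, n1 + 1)[:-1]
    right = np.linspace(x_ins, p.radius_length, n2 + 1)
    return np.concatenate([left, right]), len(left)


def make_synthetic_forearm(params: ForearmGeometryParams = ForearmGeometryParams()) -> Mesh:
    """Three-region idealised forearm mesh with named node sets.

    Node sets: ``tendon_proximal_fixed`` (free tendon end),
    ``radius_proximal_pin`` / ``radius_pin_marker`` (elbow hinge node),
    ``radius_y_restrained`` (within 10% of either bone end),
    ``radius_load`` / ``radius_distal_marker`` (anterior end),
    ``muscle_attach_distal`` / ``muscle_attach_proximal`` (Laplace Dirichlet
    surfaces), ``insertion`` (tendon-bone shared nodes).
    """
    p = params
    nc = p.n_cross
    a = p.radius_radius
    L = p.radius_length
    x_ins = p.insertion_fraction * L

    # ---- bone grid ----
    xs, patch_start = _bone_stations(p)
    ys = np.linspace(-a, a, nc)
    zs = np.linspace(-a, a, nc)
    nx = len(xs)
    bone_ids = np.arange(nx * nc * nc).reshape(nx, nc, nc)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    points = [np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)]
    n_nodes = nx * nc * nc
    bone_cells = _kuhn_split(_grid_hexes(bone_ids))
    cells = [bone_cells]
    regions = [np.full(len(bone_cells), "bone")]

    # insertion: a single transverse line of bone top-surface nodes (a
    # piano-hinge connection, like the narrow ridge of a tuberosity
    # insertion).  Sharing a full surface patch instead would make the
    # nearly-incompressible tendon strap act as a moment bracket that
    # resists elbow rotation.
    insertion_row = bone_ids[patch_start, :, nc - 1]

    # ---- chain grid (distal tendon -> muscle -> proximal tendon) ----
    z0 = a
    n_t = max(2, int(round(p.tendon_length / p.edge_length)))
    n_m = max(4, int(round(p.muscle_length / p.edge_length)))
    z_levels = np.concatenate([
        [z0],
        z0 + p.tendon_length * np.arange(1, n_t + 1) / n_t,
        z0 + p.tendon_length + p.muscle_length * np.arange(1, n_m + 1) / n_m,
        z0 + p.tendon_length + p.muscle_length
        + p.tendon_length * np.arange(1, n_t + 1) / n_t,
    ])
    nz = len(z_levels)
    chain_ids = np.empty((nc, nc, nz), dtype=np.int64)
    # bottom face: the centre x-row is the shared insertion line; the other
    # rows are chain-own nodes resting on the bone surface plane
    c_mid = nc // 2
    sec0 = _chain_section(p, z_levels[0], z0)
    bottom = np.empty((nc, nc), dtype=np.int64)
    for i in range(nc):
        if i == c_mid:
            bottom[i] = insertion_row
            continue
        ids_row = n_nodes + np.arange(nc)
        row_pts = np.empty((nc, 3))
        row = sec0.reshape(nc, nc, 2)[i]
        row_pts[:, 0] = x_ins + row[:, 0]
        row_pts[:, 1] = row[:, 1]
        row_pts[:, 2] = z_levels[0]
        points.append(row_pts)
        bottom[i] = ids_row
        n_nodes += nc
    chain_ids[:, :, 0] = bottom
    for k in range(1, nz):
        chain_ids[:, :, k] = n_nodes + np.arange(nc * nc).reshape(nc, nc)
        sec = _chain_section(p, z_levels[k], z0)
        pts_k = np.empty((nc * nc, 3))
        pts_k[:, 0] = x_ins + sec[:, 0]
        pts_k[:, 1] = sec[:, 1]
        pts_k[:, 2] = z_levels[k]
        points.append(pts_k)
        n_nodes += nc * nc
    chain_cells = _kuhn_split(_grid_hexes(chain_ids))
    cells.append(chain_cells)
    # the contractile muscle belly excludes the aponeurotic end cones
    k_lo = int(round(p.aponeurosis_fraction * n_m))
    k_hi = n_m - k_lo
    interval_region = np.full(nz - 1, "tendon", dtype=object)
    interval_region[n_t + k_lo: n_t + k_hi] = "muscle"
    # hex ordering from _grid_hexes varies the z interval fastest
    hex_region = np.broadcast_to(
        interval_region[None, None, :], (nc - 1, nc - 1, nz - 1)
    ).ravel()
    regions.append(np.repeat(hex_region.astype("U6"), 6))

    pts = np.concatenate(points)
    cls = np.concatenate(cells)
    reg = np.concatenate(regions)
    cls = _fix_orientation(pts, cls)

    c = nc // 2
    sets = {
        "radius_proximal_pin": np.array([bone_ids[0, c, c]]),
        "radius_pin_marker": np.array([bone_ids[0, c, c]]),
        "radius_distal_marker": np.array([bone_ids[nx - 1, c, c]]),
        "radius_load": bone_ids[nx - 1].ravel(),
        "radius_y_restrained": bone_ids[
            (xs <= 0.1 * L) | (xs >= 0.9 * L)
        ].ravel(),
        "insertion": insertion_row.copy(),
        "muscle_attach_distal": chain_ids[:, :, n_t + k_lo].ravel(),
        "muscle_attach_proximal": chain_ids[:, :, n_t + k_hi].ravel(),
        "tendon_proximal_fixed": chain_ids[:, :, nz - 1].ravel(),
    }
    mesh = Mesh(pts, cls, reg, sets)

    if p.jitter > 0.0:
        rng = np.random.default_rng(p.seed)
        interior = _interior_nodes(mesh)
        protected = np.unique(np.concatenate(list(sets.values())))
        interior = np.setdiff1d(interior, protected)
        mesh.points[interior] += rng.uniform(
            -p.jitter, p.jitter, size=(len(interior), 3)
        )
        mesh.cells = _fix_orientation(mesh.points, mesh.cells)

    mesh.validate()
    if mesh.n_elements < 200:
        raise ValueError("edge_length too coarse: fewer than 200 elements")
    return mesh


def _interior_nodes(mesh: Mesh) -> np.ndarray:
    faces = np.sort(
        mesh.cells[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3),
        axis=1,
    )
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    boundary_nodes = np.unique(uniq[counts == 1])
    return np.setdiff1d(np.arange(mesh.n_nodes), boundary_nodes)


def _ring_area(sec: np.ndarray, nc: int) -> float:
    """Shoelace area of the boundary ring of an (nc x nc) section grid."""
    g = sec.reshape(nc, nc, 2)
    ring = np.concatenate([
        g[:, 0], g[-1, 1:], g[-2::-1, -1], g[0, -2:0:-1],
    ])
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def generative_region_volumes(params: ForearmGeometryParams, n_quad: int = 400) -> dict:
    """Volumes (mm^3) of the generative solids, by fine axial quadrature.

    The generative sections are the polygonal (squircle-mapped) sections the
    mesh is built from, integrated along the axis with ``n_quad`` stations.
    """
    p = params
    a = p.radius_radius
    out = {"bone": (2.0 * a) ** 2 * p.radius_length}
    z0 = a
    z3 = z0 + 2 * p.tendon_length + p.muscle_length

    def area(z):
        return _ring_area(_chain_section(p, z, z0), p.n_cross)

    def piece(za, zb):
        zq = np.linspace(za, zb, n_quad)
        return float(np.trapezoid([area(z) for z in zq], zq))

    z1, z2 = z0 + p.tendon_length, z0 + p.tendon_length + p.muscle_length
    n_m = max(4, int(round(p.muscle_length / p.edge_length)))
    k_lo = int(round(p.aponeurosis_fraction * n_m))
    za = z1 + p.muscle_length * k_lo / n_m
    zb = z2 - p.muscle_length * k_lo / n_m
    out["muscle"] = piece(za, zb)
    out["tendon"] = piece(z0, za) + piece(zb, z3)
    return out


def region_volumes(mesh: Mesh) -> dict:
    v = mesh.volumes()
    return {str(r): float(v[mesh.region == r].sum()) for r in np.unique(mesh.region)}


def min_dihedral_angle(mesh: Mesh) -> float:
    """Minimum dihedral angle over all tetrahedra (degrees)."""
    x = mesh.points[mesh.cells]
    worst = 180.0
    # dihedral at edge (i, j) between the two faces through k and l
    edges = [(0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2),
             (1, 2, 0, 3), (1, 3, 0, 2), (2, 3, 0, 1)]
    for i, j, k, l in edges:
        e = x[:, j] - x[:, i]
        n1 = np.cross(e, x[:, k] - x[:, i])
        n2 = np.cross(e, x[:, l] - x[:, i])
        c = np.einsum("ei,ei->e", n1, n2) / (
            np.linalg.norm(n1, axis=1) * np.linalg.norm(n2, axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
        worst = min(worst, float(ang.min()))
    return worst


# ---------------------------------------------------------------------------
# Mesh file I/O (Gmsh MSH v2.2 ASCII and legacy VTK ASCII)
# ---------------------------------------------------------------------------

def write_mesh(mesh: Mesh, path, fmt: str = None, point_data: dict = None,
               cell_data: dict = None) -> None:
    """Write a mesh; format inferred from the suffix (.msh or .vtk).

    ``point_data`` / ``cell_data`` (named float arrays, VTK only) attach
    result fields for visualisation.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "msh":
        _write_msh22(mesh, path)
    elif fmt == "vtk":
        _write_vtk(mesh, path, point_data or {}, cell_data or {})
    else:
        raise MeshIOError(f"unsupported mesh format {fmt!r} (use msh or vtk)")


def read_mesh(path, fmt: str = None) -> Mesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "msh":
        return _read_msh22(path)
    if fmt == "vtk":
        return _read_vtk(path)
    raise MeshIOError(f"unsupported mesh format {fmt!r} (use msh or vtk)")


def _write_msh22(mesh: Mesh, path: Path) -> None:
    region_names = sorted(set(mesh.region.tolist()))
    region_tag = {r: i + 1 for i, r in enumerate(region_names)}
    set_names = sorted(mesh.node_sets)
    set_tag = {s: len(region_names) + i + 1 for i, s in enumerate(set_names)}
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(region_names) + len(set_names))]
    for r in region_names:
        lines.append(f'3 {region_tag[r]} "{r}"')
    for s in set_names:
        lines.append(f'0 {set_tag[s]} "{s}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, pt in enumerate(mesh.points, start=1):
        lines.append(f"{i} {pt[0]:.17g} {pt[1]:.17g} {pt[2]:.17g}")
    lines.append("$EndNodes")
    n_pts_elems = sum(len(v) for v in mesh.node_sets.values())
    lines.append("$Elements")
    lines.append(str(n_pts_elems + mesh.n_elements))
    eid = 1
    for s in set_names:
        for node in mesh.node_sets[s]:
            lines.append(f"{eid} 15 2 {set_tag[s]} {set_tag[s]} {node + 1}")
            eid += 1
    for cell, r in zip(mesh.cells, mesh.region):
        t = region_tag[str(r)]
        lines.append(
            f"{eid} 4 2 {t} {t} {cell[0]+1} {cell[1]+1} {cell[2]+1} {cell[3]+1}"
        )
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh22(path: Path) -> Mesh:
    text = path.read_text().split("\n")
    sections = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            while j < len(text) and text[j].strip() != f"$End{name}":
                j += 1
            if j == len(text):
                raise MeshIOError(f"unterminated section {name} in {path}")
            sections[name] = text[i + 1: j]
            i = j + 1
        else:
            i += 1
    for required in ("MeshFormat", "Nodes", "Elements"):
        if required not in sections:
            raise MeshIOError(f"missing ${required} section in {path}")
    if not sections["MeshFormat"][0].split()[0].startswith("2.2"):
        raise MeshIOError(
            f"unsupported MSH version {sections['MeshFormat'][0].split()[0]} "
            "(only v2.2 ASCII is supported)"
        )
    names_3d, names_0d = {}, {}
    for line in sections.get("PhysicalNames", [])[1:]:
        parts = line.split(None, 2)
        if len(parts) < 3:
            continue
        dim, tag, name = int(parts[0]), int(parts[1]), parts[2].strip().strip('"')
        (names_3d if dim == 3 else names_0d)[tag] = name
    nn = int(sections["Nodes"][0])
    pts = np.empty((nn, 3))
    for line in sections["Nodes"][1: nn + 1]:
        parts = line.split()
        pts[int(parts[0]) - 1] = [float(parts[1]), float(parts[2]), float(parts[3])]
    ne = int(sections["Elements"][0])
    cells, regions = [], []
    node_sets: dict = {}
    for line in sections["Elements"][1: ne + 1]:
        parts = [int(v) for v in line.split()]
        etype, ntags = parts[1], parts[2]
        tags = parts[3: 3 + ntags]
        nodes = parts[3 + ntags:]
        if etype == 4:
            if not tags or tags[0] not in names_3d:
                raise MeshIOError(
                    f"tetrahedron without a named physical region in {path}"
                )
            cells.append([n - 1 for n in nodes])
            regions.append(names_3d[tags[0]])
        elif etype == 15:
            if tags and tags[0] in names_0d:
                node_sets.setdefault(names_0d[tags[0]], []).append(nodes[0] - 1)
    if not cells:
        raise MeshIOError(f"no tetrahedra found in {path}")
    sets = {k: np.array(sorted(v), dtype=np.int64) for k, v in node_sets.items()}
    return Mesh(pts, np.array(cells), np.array(regions), sets)


def _write_vtk(mesh: Mesh, path: Path, point_data: dict, cell_data: dict) -> None:
    region_names = sorted(set(mesh.region.tolist()))
    region_tag = {r: i + 1 for i, r in enumerate(region_names)}
    title = "myoflex regions=" + ",".join(f"{r}:{region_tag[r]}" for r in region_names)
    out = ["# vtk DataFile Version 3.0", title[:255], "ASCII",
           "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double"]
    for pt in mesh.points:
        out.append(f"{pt[0]:.17g} {pt[1]:.17g} {pt[2]:.17g}")
    out.append(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}")
    for cell in mesh.cells:
        out.append(f"4 {cell[0]} {cell[1]} {cell[2]} {cell[3]}")
    out.append(f"CELL_TYPES {mesh.n_elements}")
    out.extend(["10"] * mesh.n_elements)
    out.append(f"CELL_DATA {mesh.n_elements}")
    out.append("SCALARS region int 1")
    out.append("LOOKUP_TABLE default")
    out.extend(str(region_tag[str(r)]) for r in mesh.region)
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if arr.ndim == 2 and arr.shape[1] == 3:
            out.append(f"VECTORS {name} double")
            out.extend(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in arr)
        else:
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out.extend(f"{v:.17g}" for v in arr)
    out.append(f"POINT_DATA {mesh.n_nodes}")
    for s in sorted(mesh.node_sets):
        flags = np.zeros(mesh.n_nodes, dtype=int)
        flags[mesh.node_sets[s]] = 1
        out.append(f"SCALARS set_{s} int 1")
        out.append("LOOKUP_TABLE default")
        out.extend(str(v) for v in flags)
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        if arr.ndim == 2 and arr.shape[1] == 3:
            out.append(f"VECTORS {name} double")
            out.extend(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in arr)
        else:
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out.extend(f"{v:.17g}" for v in arr)
    path.write_text("\n".join(out) + "\n")


def _read_vtk(path: Path) -> Mesh:
    lines = path.read_text().split("\n")
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise MeshIOError(f"not a legacy VTK file: {path}")
    if "regions=" not in lines[1]:
        raise MeshIOError(f"VTK file lacks the region-name mapping: {path}")
    tag_to_region = {}
    for pair in lines[1].split("regions=")[1].split(","):
        name, tag = pair.split(":")
        tag_to_region[int(tag)] = name
    i = 0
    pts = cells = region_ids = None
    node_sets = {}
    n_nodes = 0
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "POINTS":
            n_nodes = int(tok[1])
            vals = " ".join(lines[i + 1: i + 1 + n_nodes]).split()
            pts = np.array(vals, dtype=float).reshape(n_nodes, 3)
            i += 1 + n_nodes
        elif tok[0] == "CELLS":
            m = int(tok[1])
            rows = [lines[i + 1 + k].split() for k in range(m)]
            cells = np.array([[int(v) for v in r[1:5]] for r in rows])
            i += 1 + m
        elif tok[0] == "SCALARS" and tok[1] == "region":
            m = len(cells)
            region_ids = np.array(
                " ".join(lines[i + 2: i + 2 + m]).split(), dtype=int
            )
            i += 2 + m
        elif tok[0] == "SCALARS" and tok[1].startswith("set_"):
            flags = np.array(
                " ".join(lines[i + 2: i + 2 + n_nodes]).split(), dtype=int
            )
            node_sets[tok[1][4:]] = np.nonzero(flags)[0].astype(np.int64)
            i += 2 + n_nodes
        else:
            i += 1
    if pts is None or cells is None:
        raise MeshIOError(f"incomplete VTK unstructured grid in {path}")
    if region_ids is None:
        raise MeshIOError(f"VTK file lacks the region cell array: {path}")
    region = np.array([tag_to_region[t] for t in region_ids])
    return Mesh(pts, cells, region, node_sets)
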