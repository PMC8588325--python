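"""Tagged triangular meshes for the forward and inverse problems.

The mesher places nodes on all tissue contours (resampled at the target
edge length), fills the interior of the computational disc with a
hexagonal lattice, and triangulates the combined point set with a
Delaunay tessellation.  Because every contour is sampled at the mesh
scale, Delaunay edges follow the material boundaries to within O(h²),
which is sufficient for linear elements; triangles are tagged by the
region containing their centroid.

Mesh sizing follows the wavelength rule: the characteristic edge length
is λ/10 with λ = c / (f √ε_r,max), ε_r,max being the largest real
relative permittivity anywhere in the scene (tissues and matching
medium included).  Forward and inversion meshes are generated at
different length scales so that inversions never run on the same
discretization that produced the data (inverse-crime guard).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay, cKDTree
from shapely import contains_xy
from shapely.geometry import Polygon

from .phantoms import PhantomModel

__all__ = [
    "SPEED_OF_LIGHT",
    "MESH_SIZE_FACTOR",
    "REGION_CODES",
    "REGION_LABELS",
    "MeshingError",
    "TriMesh",
    "ImagingDomain",
    "characteristic_length",
    "delaunay_mesh",
    "generate_mesh",
    "extract_imaging_domain",
    "barycentric_sampling_matrix",
    "write_msh",
    "read_msh",
    "write_node_ele",
    "read_node_ele",
]

SPEED_OF_LIGHT = 3.0e8  # m/s

#: Safety factor applied to the λ/10 bound when generating meshes: the
#: point-cloud Delaunay mesher yields less regular triangles than a
#: frontal mesher, and the sizing rule is an upper bound ("smaller than
#: λ/10"), so default meshes are built at 0.8 × the bound.
MESH_SIZE_FACTOR = 0.8

#: Physical-group integer per region label (MSH files store these).
REGION_CODES: dict[str, int] = {
    "medium": 0,
    "skin": 1,
    "fat": 2,
    "muscle": 3,
    "tibia": 4,
    "fibula": 5,
}
REGION_LABELS: tuple[str, ...] = tuple(REGION_CODES)


class MeshingError(RuntimeError):
    """Raised for degenerate contours or failed triangulations."""


def characteristic_length(frequency: float, eps_r_max: float) -> float:
    """Target mesh edge length λ/10 from the wavelength sizing rule.

    λ = c / (f √ε_r,max) with c = 3×10⁸ m/s; ε_r_max is the largest
    real relative permittivity present in the model.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if eps_r_max < 1.0:
        raise ValueError("eps_r_max must be ≥ 1")
    wavelength = SPEED_OF_LIGHT / (frequency * np.sqrt(eps_r_max))
    return wavelength / 10.0


@dataclass(frozen=True)
class TriMesh:
    """Conforming linear-triangle mesh with per-triangle region tags."""

    nodes: np.ndarray          # (N, 2) float, meters
    triangles: np.ndarray      # (M, 3) int, CCW
    region_tags: np.ndarray    # (M,) int, see REGION_CODES
    boundary_edges: np.ndarray  # (B, 2) int node pairs on the outer boundary
    characteristic_length: float

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_triangles(self) -> int:
        return len(self.triangles)

    def triangle_coords(self) -> np.ndarray:
        """(M, 3, 2) vertex coordinates per triangle."""
        return self.nodes[self.triangles]

    def areas(self) -> np.ndarray:
        xy = self.triangle_coords()
        d1 = xy[:, 1] - xy[:, 0]
        d2 = xy[:, 2] - xy[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def centroids(self) -> np.ndarray:
        return self.triangle_coords().mean(axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) sorted-index array."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)

    def labels(self) -> np.ndarray:
        """Per-triangle region labels as strings."""
        inv = {v: k for k, v in REGION_CODES.items()}
        return np.array([inv[c] for c in self.region_tags])


@dataclass(frozen=True)
class ImagingDomain:
    """Inversion-mesh nodes lying inside the leg (domain D)."""

    node_indices: np.ndarray  # indices into the inversion mesh, sorted
    total_nodes: int          # N of the inversion mesh

    @property
    def size(self) -> int:
        """I, the number of contrast unknowns."""
        return len(self.node_indices)


def _resample_section(a: np.ndarray, spacing: float) -> np.ndarray:
    """Arc-length resample an open polyline section, excluding its end."""
    seg = np.linalg.norm(np.diff(a, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(1, int(np.round(total / spacing)))
    t = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack([np.interp(t, s, a[:, 0]), np.interp(t, s, a[:, 1])])


def _resample_closed(poly: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed polyline at ~uniform spacing.

    Corner vertices (turning angle > 30°) are always preserved so that
    polygonal shapes keep their area; smooth sections between corners
    are resampled by arc length at the target spacing.
    """
    p = np.asarray(poly, dtype=float)
    if len(p) < 3:
        raise MeshingError("contour needs at least 3 points")
    seg_out = np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)
    if seg_out.sum() <= 0:
        raise MeshingError("degenerate (zero-length) contour")
    if np.any(seg_out == 0):
        keep = seg_out > 0
        p = p[keep]
        seg_out = np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)
    d_in = p - np.roll(p, 1, axis=0)
    d_out = np.roll(p, -1, axis=0) - p
    cosang = np.sum(d_in * d_out, axis=1) / (
        np.linalg.norm(d_in, axis=1) * np.linalg.norm(d_out, axis=1))
    corners = np.flatnonzero(cosang < np.cos(np.radians(30.0)) - 1e-12)

    if len(corners) == 0:
        closed = np.vstack([p, p[:1]])
        return _resample_section(closed, spacing)
    out = []
    for i, c in enumerate(corners):
        nxt = corners[(i + 1) % len(corners)]
        if nxt > c:
            section = p[c:nxt + 1]
        else:  # wraps around the closure point
            section = np.vstack([p[c:], p[:nxt + 1]])
        out.append(_resample_section(section, spacing))
    return np.vstack(out)


def _hex_lattice(bbox: tuple[float, float, float, float], h: float) -> np.ndarray:
    """Hexagonal point lattice with spacing h covering the bbox."""
    xmin, ymin, xmax, ymax = bbox
    dy = h * np.sqrt(3.0) / 2.0
    rows = []
    ny = int(np.ceil((ymax - ymin) / dy)) + 1
    nx = int(np.ceil((xmax - xmin) / h)) + 2
    for iy in range(ny):
        y = ymin + iy * dy
        offset = 0.5 * h if iy % 2 else 0.0
        x = xmin + offset + h * np.arange(nx)
        rows.append(np.column_stack([x, np.full_like(x, y)]))
    pts = np.vstack(rows)
    keep = (pts[:, 0] <= xmax + h) & (pts[:, 1] <= ymax + dy)
    return pts[keep]


def delaunay_mesh(
    boundary: np.ndarray,
    length_scale: float,
    internal_contours: tuple[np.ndarray, ...] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the interior of a closed boundary polyline.

    Nodes are placed on the boundary and on every internal contour at
    the requested spacing, plus a hexagonal interior lattice kept clear
    of the contours; the point cloud is Delaunay-triangulated and
    triangles outside the boundary are discarded.

    Returns
    -------
    (nodes, triangles)
        Nodes (N, 2) and CCW triangles (M, 3).
    """
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    h = float(length_scale)
    ring_pts = [_resample_closed(boundary, 0.95 * h)]
    for c in internal_contours:
        ring_pts.append(_resample_closed(c, 0.95 * h))
    fixed = np.vstack(ring_pts)

    poly = Polygon(np.asarray(boundary, dtype=float))
    if not poly.is_valid or poly.area <= 0:
        raise MeshingError("invalid boundary polygon")
    xmin, ymin, xmax, ymax = poly.bounds
    lattice = _hex_lattice((xmin, ymin, xmax, ymax), h)
    inside = contains_xy(poly.buffer(-0.55 * h), lattice[:, 0], lattice[:, 1])
    lattice = lattice[inside]
    if len(lattice):
        tree = cKDTree(fixed)
        d, _ = tree.query(lattice, k=1)
        lattice = lattice[d >= 0.55 * h]

    points = np.vstack([fixed, lattice]) if len(lattice) else fixed
    # deduplicate (contours may touch)
    scale = max(xmax - xmin, ymax - ymin)
    key = np.round(points / (1e-12 * scale)).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    points = points[np.sort(idx)]

    tri = Delaunay(points)
    simplices = tri.simplices
    cents = points[simplices].mean(axis=1)
    keep = contains_xy(poly.buffer(1e-9 * scale), cents[:, 0], cents[:, 1])
    simplices = simplices[keep]
    if len(simplices) == 0:
        raise MeshingError("triangulation produced no interior triangles")

    # enforce CCW orientation and drop degenerate slivers
    xy = points[simplices]
    areas = 0.5 * ((xy[:, 1, 0] - xy[:, 0, 0]) * (xy[:, 2, 1] - xy[:, 0, 1])
                   - (xy[:, 1, 1] - xy[:, 0, 1]) * (xy[:, 2, 0] - xy[:, 0, 0]))
    flip = areas < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]
    simplices = simplices[np.abs(areas) > 1e-9 * h * h]

    # drop nodes not referenced by any kept triangle
    used = np.unique(simplices)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    return points[used], remap[simplices]


def _boundary_edges(triangles: np.ndarray) -> np.ndarray:
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    es = np.sort(e, axis=1)
    uniq, counts = np.unique(es, axis=0, return_counts=True)
    return uniq[counts == 1]


def _tag_regions(model: PhantomModel, centroids: np.ndarray) -> np.ndarray:
    tags = np.zeros(len(centroids), dtype=int)  # medium by default
    # outer-to-inner so inner regions overwrite
    for label in ("skin", "fat", "muscle", "tibia", "fibula"):
        poly = model.region(label).polygon().buffer(1e-12)
        mask = contains_xy(poly, centroids[:, 0], centroids[:, 1])
        tags[mask] = REGION_CODES[label]
    return tags


def generate_mesh(
    model: PhantomModel,
    length_scale: float,
    padding_radius: float,
) -> TriMesh:
    """Mesh the circular computational disc around a phantom.

    The disc of radius ``padding_radius`` (centered at the origin, which
    must enclose all antennas with margin) is triangulated with every
    tissue contour represented in the node set; triangles are tagged by
    the region containing their centroid.  Deterministic for fixed
    inputs.
    """
    if padding_radius <= 0:
        raise ValueError("padding_radius must be positive")
    theta = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
    outer = padding_radius * np.column_stack([np.cos(theta), np.sin(theta)])
    contours = tuple(r.contour for r in model.regions)
    nodes, triangles = delaunay_mesh(outer, length_scale, contours)
    mesh = TriMesh(
        nodes=nodes,
        triangles=triangles,
        region_tags=_tag_regions(model, nodes[triangles].mean(axis=1)),
        boundary_edges=_boundary_edges(triangles),
        characteristic_length=float(length_scale),
    )
    if mesh.edge_lengths().max() > 2.0 * length_scale:
        raise MeshingError("mesh contains edges far above the target length")
    return mesh


def extract_imaging_domain(mesh: TriMesh, skin_contour: np.ndarray) -> ImagingDomain:
    """Select the mesh nodes inside (or on) the leg's skin contour."""
    poly = Polygon(np.asarray(skin_contour, dtype=float))
    if not poly.is_valid or poly.area <= 0:
        raise MeshingError("invalid skin contour")
    scale = max(np.ptp(mesh.nodes[:, 0]), np.ptp(mesh.nodes[:, 1]))
    inside = contains_xy(poly.buffer(1e-9 * scale), mesh.nodes[:, 0], mesh.nodes[:, 1])
    idx = np.flatnonzero(inside)
    if len(idx) == 0:
        raise MeshingError("imaging domain is empty: contour encloses no node")
    return ImagingDomain(node_indices=idx, total_nodes=mesh.num_nodes)


def barycentric_sampling_matrix(mesh: TriMesh, points: np.ndarray) -> sp.csr_matrix:
    """Sparse (P × N) interpolation operator sampling nodal fields at points.

    Each row holds the barycentric weights of the triangle containing
    the point (weights sum to one).  Points outside the mesh raise.
    """
    from matplotlib.tri import Triangulation, TrapezoidMapTriFinder

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    triang = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles)
    finder = TrapezoidMapTriFinder(triang)
    t_idx = finder(pts[:, 0], pts[:, 1])
    if np.any(t_idx < 0):
        bad = pts[t_idx < 0]
        raise ValueError(f"{len(bad)} sampling point(s) outside the mesh, e.g. {bad[0]}")
    rows, cols, vals = [], [], []
    for i, (p, t) in enumerate(zip(pts, t_idx)):
        v = mesh.triangles[t]
        xy = mesh.nodes[v]
        T = np.column_stack([xy[1] - xy[0], xy[2] - xy[0]])
        lam12 = np.linalg.solve(T, p - xy[0])
        lam = np.array([1.0 - lam12.sum(), lam12[0], lam12[1]])
        rows.extend([i] * 3)
        cols.extend(v.tolist())
        vals.extend(lam.tolist())
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(pts), mesh.num_nodes))


# ---------------------------------------------------------------------------
# file formats

def write_msh(mesh: TriMesh, path: str | Path) -> None:
    """Write the mesh as Gmsh MSH 2.2 ASCII (triangles carry the region
    code as their physical/geometric tags)."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.num_nodes)]
    for i, (x, y) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.17g} {y:.17g} 0")
    lines += ["$EndNodes", "$Elements", str(mesh.num_triangles)]
    for i, (tri, tag) in enumerate(zip(mesh.triangles, mesh.region_tags), start=1):
        a, b, c = (int(v) + 1 for v in tri)
        lines.append(f"{i} 2 2 {int(tag)} {int(tag)} {a} {b} {c}")
    lines += ["$EndElements", ""]
    Path(path).write_text("\n".join(lines))


def read_msh(path: str | Path, characteristic_length: float = np.nan) -> TriMesh:
    """Read a (2D, triangles-only) Gmsh MSH 2.2 ASCII file."""
    tokens = Path(path).read_text().splitlines()
    it = iter(tokens)
    nodes, tris, tags = [], [], []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(parts[1]), float(parts[2])])
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                if int(parts[1]) != 2:  # keep triangles only
                    continue
                ntags = int(parts[2])
                tags.append(int(parts[3]) if ntags else 0)
                v = [int(x) - 1 for x in parts[3 + ntags:6 + ntags]]
                tris.append(v)
    triangles = np.asarray(tris, dtype=int)
    return TriMesh(
        nodes=np.asarray(nodes, dtype=float),
        triangles=triangles,
        region_tags=np.asarray(tags, dtype=int),
        boundary_edges=_boundary_edges(triangles),
        characteristic_length=float(characteristic_length),
    )


def write_node_ele(mesh: TriMesh, stem: str | Path) -> tuple[Path, Path]:
    """Write minimal Triangle-style ``.node``/``.ele`` text files."""
    stem = Path(stem)
    node_path = stem.with_suffix(".node")
    ele_path = stem.with_suffix(".ele")
    with open(node_path, "w") as fh:
        fh.write(f"{mesh.num_nodes} 2 0 0\n")
        for i, (x, y) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {x:.17g} {y:.17g}\n")
    with open(ele_path, "w") as fh:
        fh.write(f"{mesh.num_triangles} 3 1\n")
        for i, (tri, tag) in enumerate(zip(mesh.triangles, mesh.region_tags), start=1):
            fh.write(f"{i} {tri[0]+1} {tri[1]+1} {tri[2]+1} {int(tag)}\n")
    return node_path, ele_path


def read_node_ele(stem: str | Path, characteristic_length: float = np.nan) -> TriMesh:
    """Read the ``.node``/``.ele`` pair written by :func:`write_node_ele`."""
    stem = Path(stem)
    node_lines = stem.with_suffix(".node").read_text().splitlines()
    n = int(node_lines[0].split()[0])
    nodes = np.array([[float(v) for v in ln.split()[1:3]] for ln in node_lines[1:1 + n]])
    ele_lines = stem.with_suffix(".ele").read_text().splitlines()
    m = int(ele_lines[0].split()[0])
    tris, tags = [], []
    for ln in ele_lines[1:1 + m]:
        parts = ln.split()
        tris.append([int(parts[1]) - 1, int(parts[2]) - 1, int(parts[3]) - 1])
        tags.append(int(parts[4]) if len(parts) > 4 else 0)
    triangles = np.asarray(tris, dtype=int)
    return TriMesh(
        nodes=nodes,
        triangles=triangles,
        region_tags=np.asarray(tags, dtype=int),
        boundary_edges=_boundary_edges(triangles),
        characteristic_length=float(characteristic_length),
    )
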