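"""Triangulated platelet surface meshes.

A resting platelet is modelled as an oblate spheroid
``x^2/a^2 + y^2/a^2 + z^2/(lambda a)^2 = 1`` whose surface is triangulated
into N vertices (default 958).  Vertices double as coarse-grained actin
nodes of the cytoskeleton spring network; GPIb-alpha receptor sites are
independent points sampled uniformly on the surface and tied to their
containing triangle through barycentric coordinates (sites can outnumber
vertices; bond forces at a site are distributed to the triangle vertices by
the barycentric weights).

The triangulation uses a Fibonacci lattice on the unit sphere mapped to the
ellipsoid and triangulated by its convex hull, which realises any vertex
count exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull


@dataclass
class PlateletMesh:
    """Closed triangulated platelet surface with rest-state geometry.

    Attributes
    ----------
    vertices : (N, 3) float array, positions (m).
    triangles : (M, 3) int array, outward-oriented vertex index triples.
    edges : (E, 2) int array, unique undirected edges.
    rest_lengths : (E,) float, edge lengths in the unstressed state (m).
    ref_triangle_areas : (M,) float, unstressed triangle areas (m^2).
    ref_area, ref_volume : unstressed totals (m^2, m^3).
    receptor_sites : (S, 2) int/float structure split into
        ``site_triangles`` (S,) int and ``site_bary`` (S, 3) float;
        ``receptors_per_site`` defaults to 2 (two GPIb-alpha per GPV).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    edges: np.ndarray = field(default=None)  # type: ignore[assignment]
    rest_lengths: np.ndarray = field(default=None)  # type: ignore[assignment]
    ref_triangle_areas: np.ndarray = field(default=None)  # type: ignore[assignment]
    ref_area: float = 0.0
    ref_volume: float = 0.0
    site_triangles: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    site_bary: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    receptors_per_site: int = 2

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.edges is None:
            self.edges = unique_edges(self.triangles)
        if self.rest_lengths is None:
            self.rest_lengths = edge_lengths(self.vertices, self.edges)
        if self.ref_triangle_areas is None:
            self.ref_triangle_areas = triangle_areas(self.vertices, self.triangles)
        if not self.ref_area:
            self.ref_area = float(self.ref_triangle_areas.sum())
        if not self.ref_volume:
            self.ref_volume = mesh_volume(self.vertices, self.triangles)

    # -- basic queries -----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_sites(self) -> int:
        return len(self.site_triangles)

    @property
    def n_receptors(self) -> int:
        return self.n_sites * self.receptors_per_site

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + len(self.triangles)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def site_positions(self) -> np.ndarray:
        """World coordinates of receptor sites from barycentric coordinates."""
        if self.n_sites == 0:
            return np.empty((0, 3))
        tri = self.vertices[self.triangles[self.site_triangles]]  # (S,3,3)
        return np.einsum("sk,skj->sj", self.site_bary, tri)

    def copy(self) -> "PlateletMesh":
        return PlateletMesh(
            vertices=self.vertices.copy(),
            triangles=self.triangles.copy(),
            edges=self.edges.copy(),
            rest_lengths=self.rest_lengths.copy(),
            ref_triangle_areas=self.ref_triangle_areas.copy(),
            ref_area=self.ref_area,
            ref_volume=self.ref_volume,
            site_triangles=self.site_triangles.copy(),
            site_bary=self.site_bary.copy(),
            receptors_per_site=self.receptors_per_site,
        )


# ---------------------------------------------------------------------------
# geometry helpers


def cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product of (N, 3) arrays (avoids np.cross overhead)."""
    c = np.empty_like(a)
    c[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    c[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    c[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return c


def scatter_add(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """out[idx] += vals with repeated indices, via bincount (faster than
    np.add.at for the scatter sizes used here)."""
    n = len(out)
    if out.ndim == 1:
        out += np.bincount(idx, weights=vals, minlength=n)
        return
    for k in range(out.shape[1]):
        out[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


def unique_edges(triangles: np.ndarray) -> np.ndarray:
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def edge_lengths(vertices: np.ndarray, edges: np.ndarray) -> np.ndarray:
    d = vertices[edges[:, 1]] - vertices[edges[:, 0]]
    return np.linalg.norm(d, axis=1)


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = vertices[triangles]
    cross = cross3(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.sqrt(np.einsum("ij,ij->i", cross, cross))


def triangle_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Unit normals of outward-oriented triangles."""
    p = vertices[triangles]
    cross = cross3(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    n = np.linalg.norm(cross, axis=1, keepdims=True)
    return cross / n


def mesh_volume(vertices: np.ndarray, triangles: np.ndarray) -> float:
    """Signed volume by summing tetrahedra against the origin (positive for
    outward orientation); translation invariant for closed meshes."""
    c = vertices.mean(axis=0)
    p = vertices[triangles] - c
    return float(np.einsum("ij,ij->", p[:, 0], np.cross(p[:, 1], p[:, 2])) / 6.0)


def mesh_area_volume(mesh: PlateletMesh) -> tuple[float, float]:
    """Total surface area (m^2) and enclosed volume (m^3) of a closed mesh."""
    check_closed(mesh)
    area = float(triangle_areas(mesh.vertices, mesh.triangles).sum())
    vol = mesh_volume(mesh.vertices, mesh.triangles)
    if vol <= 0:
        raise ValueError("mesh has negative signed volume; orientation is inward")
    return area, vol


def check_closed(mesh: PlateletMesh) -> None:
    """Raise if the mesh is not a closed orientable 2-manifold."""
    tri = mesh.triangles
    directed = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise ValueError("mesh is not closed: some edges not shared by 2 triangles")
    if mesh.euler_characteristic() != 2:
        raise ValueError(
            f"Euler characteristic {mesh.euler_characteristic()} != 2"
        )


def vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Area-weighted outward vertex normals (unit length)."""
    p = vertices[triangles]
    cross = cross3(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # 2*area*normal
    n = np.zeros_like(vertices)
    for k in range(3):
        scatter_add(n, triangles[:, k], cross)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return n / norms


def vertex_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Barycentric vertex areas (one third of incident triangle areas)."""
    a = triangle_areas(vertices, triangles)
    out = np.zeros(len(vertices))
    for k in range(3):
        scatter_add(out, triangles[:, k], a / 3.0)
    return out


# ---------------------------------------------------------------------------
# construction


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / phi
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _orient_outward(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Flip triangles so all normals point away from the centroid."""
    c = points.mean(axis=0)
    p = points[simplices]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    out = np.einsum("ij,ij->i", n, p.mean(axis=1) - c) < 0
    simplices = simplices.copy()
    simplices[out] = simplices[out][:, [0, 2, 1]]
    return simplices


def make_ellipsoid_mesh(a: float, b: float, c: float, n: int) -> PlateletMesh:
    """Triangulate the ellipsoid with semi-axes (a, b, c) using exactly n vertices."""
    if n < 12:
        raise ValueError("need at least 12 vertices for a sensible closed surface")
    pts = _fibonacci_sphere(n) * np.array([a, b, c])
    hull = ConvexHull(pts)
    if len(hull.vertices) != n:  # all points must appear on the hull
        raise ValueError(
            f"triangulation dropped {n - len(hull.vertices)} vertices; "
            "n_target unattainable with this scheme"
        )
    tris = _orient_outward(pts, hull.simplices.astype(np.int64))
    return PlateletMesh(vertices=pts, triangles=tris)


def make_platelet_mesh(
    a: float = 1.0e-6,
    lambda_ar: float = 0.25,
    n_target: int = 958,
    seed: int | None = None,
) -> PlateletMesh:
    """Oblate-spheroid platelet surface: semi-axes (a, a, lambda*a).

    The construction is deterministic; ``seed`` only matters for receptor
    placement done separately via :func:`place_receptors`.
    """
    if a <= 0 or not (0 < lambda_ar <= 1):
        raise ValueError("require a > 0 and 0 < lambda_ar <= 1")
    return make_ellipsoid_mesh(a, a, lambda_ar * a, n_target)


def place_receptors(
    mesh: PlateletMesh, n_sites: int = 5344, seed: int | None = None
) -> PlateletMesh:
    """Sample receptor sites uniformly over the surface (area-weighted).

    Each site represents ``receptors_per_site`` (2) GPIb-alpha receptors and
    is stored as (triangle index, barycentric coordinates).  Returns the same
    mesh object with sites attached.
    """
    rng = np.random.default_rng(seed)
    if n_sites == 0:
        mesh.site_triangles = np.empty(0, dtype=int)
        mesh.site_bary = np.empty((0, 3))
        return mesh
    areas = triangle_areas(mesh.vertices, mesh.triangles)
    p = areas / areas.sum()
    tri_idx = rng.choice(len(areas), size=n_sites, p=p)
    # uniform barycentric sampling inside each triangle
    r1 = np.sqrt(rng.random(n_sites))
    r2 = rng.random(n_sites)
    u = 1.0 - r1
    v = r1 * (1.0 - r2)
    w = r1 * r2
    mesh.site_triangles = tri_idx.astype(np.int64)
    mesh.site_bary = np.column_stack([u, v, w])
    return mesh


def oblate_spheroid_area(a: float, lam: float) -> float:
    """Closed-form surface area of an oblate spheroid with semi-axes (a, a, lam*a)."""
    if lam >= 1.0:
        return 4.0 * np.pi * a * a
    e = np.sqrt(1.0 - lam * lam)
    return 2.0 * np.pi * a * a * (1.0 + (1.0 - e * e) / e * np.arctanh(e))


# ---------------------------------------------------------------------------
# file IO (ASCII OFF and VTK legacy polydata)


def write_mesh(mesh: PlateletMesh, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("vtk" if path.suffix.lower() == ".vtk" else "off")
    if fmt == "off":
        _write_off(mesh, path)
    elif fmt == "vtk":
        _write_vtk(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")


def read_mesh(path: str | Path, fmt: str | None = None) -> PlateletMesh:
    path = Path(path)
    fmt = fmt or ("vtk" if path.suffix.lower() == ".vtk" else "off")
    if fmt == "off":
        return _read_off(path)
    if fmt == "vtk":
        return _read_vtk(path)
    raise ValueError(f"unsupported mesh format {fmt!r}")


def _write_off(mesh: PlateletMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.triangles)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_off(path: Path) -> PlateletMesh:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines or lines[0] != "OFF":
        raise ValueError(f"{path}:1: not an OFF file")
    try:
        nv, nf, _ = (int(x) for x in lines[1].split())
        verts = np.array([[float(x) for x in ln.split()] for ln in lines[2 : 2 + nv]])
        tris = []
        for i, ln in enumerate(lines[2 + nv : 2 + nv + nf]):
            parts = [int(x) for x in ln.split()]
            if parts[0] != 3:
                raise ValueError(f"{path}:{3 + nv + i}: non-triangular face")
            tris.append(parts[1:4])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed OFF file {path}: {exc}") from exc
    return PlateletMesh(vertices=verts, triangles=np.array(tris, dtype=np.int64))


def _write_vtk(mesh: PlateletMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nplatesim mesh\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        m = len(mesh.triangles)
        fh.write(f"POLYGONS {m} {4 * m}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_vtk(path: Path) -> PlateletMesh:
    lines = Path(path).read_text().splitlines()
    verts, tris = None, None
    i = 0
    try:
        while i < len(lines):
            ln = lines[i].strip()
            if ln.startswith("POINTS"):
                n = int(ln.split()[1])
                vals: list[float] = []
                i += 1
                while len(vals) < 3 * n:
                    vals.extend(float(x) for x in lines[i].split())
                    i += 1
                verts = np.array(vals).reshape(n, 3)
                continue
            if ln.startswith("POLYGONS"):
                m = int(ln.split()[1])
                tris = []
                for j in range(m):
                    parts = [int(x) for x in lines[i + 1 + j].split()]
                    if parts[0] != 3:
                        raise ValueError(f"line {i + 2 + j}: non-triangular face")
                    tris.append(parts[1:4])
                i += 1 + m
                continue
            i += 1
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed VTK file {path}: {exc}") from exc
    if verts is None or tris is None:
        raise ValueError(f"malformed VTK file {path}: missing POINTS/POLYGONS")
    return PlateletMesh(vertices=verts, triangles=np.array(tris, dtype=np.int64))


def write_receptor_sites(mesh: PlateletMesh, path: str | Path) -> None:
    """Export receptor sites as CSV (site_id, triangle_id, u, v, w, n_receptors)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["site_id", "triangle_id", "bary_u", "bary_v", "bary_w",
                    "n_receptors"])
        for s in range(mesh.n_sites):
            w.writerow([s, mesh.site_triangles[s],
                        *(f"{x:.17g}" for x in mesh.site_bary[s]),
                        mesh.receptors_per_site])
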