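"""Tetrahedral meshes: loading, validation, synthesis and derived geometry.

All geometry is stored in SI meters.  Loaders take an explicit
meters-per-unit scale factor so unit mistakes in mesh files surface early
(the 20 nm small-tet diagnostic downstream also catches them).  Indices are
0-based everywhere, including in files written by this module.

Supported dialects: Gmsh v2 ASCII ``.msh`` (element type 4 = tetrahedron,
type 2 = triangle; physical volume groups become compartments, physical
surface groups become patches) and the TetGen ``.node``/``.ele``/``.face``
triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as _FsPath

import numpy as np

__all__ = [
    "Mesh", "Compartment", "Patch", "EndocyticZone", "MeshStats",
    "MeshError", "MeshParseError", "MeshValidationError", "MeshResourceError",
    "load_mesh", "load_gmsh2", "load_tetgen", "write_gmsh2", "write_tetgen",
    "make_sphere_mesh", "make_box_mesh", "mesh_stats",
]


class MeshError(Exception):
    """Base class for mesh problems."""


class MeshParseError(MeshError):
    """Malformed mesh file; message names the offending line."""


class MeshValidationError(MeshError):
    """Mesh parses but violates a geometric invariant."""


class MeshResourceError(MeshError):
    """Requested mesh resolution exceeds the node budget."""


@dataclass
class Compartment:
    """Named set of tetrahedrons representing a cellular volume."""
    name: str
    tets: np.ndarray          # int indices
    volume: float             # m^3


@dataclass
class Patch:
    """Named set of surface triangles (a membrane)."""
    name: str
    tris: np.ndarray          # indices into Mesh.surface_tris
    inner: str | None = None  # inner compartment name
    outer: str | None = None  # optional outer compartment name


@dataclass
class EndocyticZone:
    """Subset of a patch's triangles from which endocytosis may occur."""
    name: str
    patch: str
    tris: np.ndarray


@dataclass
class MeshStats:
    """Per-tetrahedron size statistics (size = mean of the 6 edge lengths)."""
    edge_mean: np.ndarray       # (n_tet,) m
    hist_counts: np.ndarray
    hist_edges: np.ndarray      # m

    def fraction_below(self, threshold: float) -> float:
        return float(np.mean(self.edge_mean < threshold))


@dataclass
class Mesh:
    """A validated tetrahedral mesh with all derived geometry precomputed.

    ``tet_neighbors[k, i]`` is the tetrahedron sharing the face opposite
    local vertex ``i`` of tet ``k`` (-1 on the boundary); ``face_area`` and
    ``neighbor_dx`` are aligned the same way and hold the shared-face area
    A_{k,l} and the barycenter-barycenter distance used by the finite-volume
    diffusion rates.
    """
    vertices: np.ndarray          # (n_vert, 3) m
    tets: np.ndarray              # (n_tet, 4) int, positively oriented
    surface_tris: np.ndarray      # (n_tri, 3) int
    tri_owner: np.ndarray         # (n_tri,) owning tet
    tet_neighbors: np.ndarray     # (n_tet, 4) int, -1 = boundary
    tet_volume: np.ndarray        # (n_tet,) m^3
    tet_barycenter: np.ndarray    # (n_tet, 3) m
    face_area: np.ndarray         # (n_tet, 4) m^2
    neighbor_dx: np.ndarray       # (n_tet, 4) m (nan on boundary)
    tri_area: np.ndarray          # (n_tri,) m^2
    tri_barycenter: np.ndarray    # (n_tri, 3) m
    tri_normal: np.ndarray        # (n_tri, 3) outward unit normal
    tri_neighbors: np.ndarray     # (n_tri, 3) int, -1 = open edge
    compartments: dict[str, Compartment] = field(default_factory=dict)
    patches: dict[str, Patch] = field(default_factory=dict)
    zones: dict[str, EndocyticZone] = field(default_factory=dict)

    # ---- convenience -------------------------------------------------
    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def n_tris(self) -> int:
        return len(self.surface_tris)

    @property
    def total_volume(self) -> float:
        return float(self.tet_volume.sum())

    def tet_vertices(self, k: int) -> np.ndarray:
        return self.vertices[self.tets[k]]

    def bounding_radius(self) -> float:
        c = self.vertices.mean(axis=0)
        return float(np.linalg.norm(self.vertices - c, axis=1).max())

    def add_compartment(self, name: str, tets=None) -> Compartment:
        idx = np.arange(self.n_tets) if tets is None else np.asarray(tets, int)
        comp = Compartment(name, idx, float(self.tet_volume[idx].sum()))
        self.compartments[name] = comp
        return comp

    def add_patch(self, name: str, tris=None, inner=None, outer=None) -> Patch:
        idx = np.arange(self.n_tris) if tris is None else np.asarray(tris, int)
        p = Patch(name, idx, inner, outer)
        self.patches[name] = p
        return p

    def add_zone(self, name: str, patch: str, tris) -> EndocyticZone:
        ptris = set(self.patches[patch].tris.tolist())
        tris = np.asarray(tris, int)
        if not set(tris.tolist()) <= ptris:
            raise MeshValidationError(
                f"endocytic zone {name!r} has triangles outside patch {patch!r}")
        z = EndocyticZone(name, patch, tris)
        self.zones[name] = z
        return z

    def containing_tet(self, point, tol: float = 1e-12) -> int:
        """Brute-force point location; -1 if outside. Use geometry.walk_to
        with a start hint for anything performance sensitive."""
        from .geometry import point_in_tet
        for k in range(self.n_tets):
            if point_in_tet(self.vertices[self.tets[k]], point, tol):
                return k
        return -1


# ---------------------------------------------------------------------------
# derived geometry
# ---------------------------------------------------------------------------

_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
# face i is opposite local vertex i, wound so its normal points away from
# vertex i for a positively oriented tet


def _tet_volumes_signed(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = vertices[tets[:, 0]]
    b = vertices[tets[:, 1]] - a
    c = vertices[tets[:, 2]] - a
    d = vertices[tets[:, 3]] - a
    return np.einsum("ij,ij->i", np.cross(b, c), d) / 6.0


def build_mesh(vertices, tets, *, fix_orientation: bool = True,
               degenerate_rel: float = 1e-12) -> Mesh:
    """Assemble a Mesh from raw vertex/tet arrays, computing all derived
    geometry and enforcing positive orientation.

    Raises MeshValidationError listing the indices of zero-volume tets.
    """
    vertices = np.ascontiguousarray(vertices, dtype=float)
    tets = np.ascontiguousarray(tets, dtype=np.int64)
    vol = _tet_volumes_signed(vertices, tets)
    if fix_orientation:
        flip = vol < 0
        if flip.any():
            tets = tets.copy()
            tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
            vol = np.abs(vol)
    scale = np.abs(vol).max() if len(vol) else 0.0
    bad = np.flatnonzero(np.abs(vol) <= degenerate_rel * max(scale, 1e-300))
    if len(bad):
        raise MeshValidationError(
            f"degenerate (zero-volume) tetrahedrons at indices {bad.tolist()}")
    if (vol <= 0).any():
        raise MeshValidationError(
            f"negatively oriented tetrahedrons at indices "
            f"{np.flatnonzero(vol <= 0).tolist()}")

    n_tet = len(tets)
    bary = vertices[tets].mean(axis=1)

    # face -> (tet, local) map for adjacency
    faces = tets[:, _FACE_LOCAL]                      # (n_tet, 4, 3)
    key = np.sort(faces.reshape(-1, 3), axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    sorted_key = key[order]
    neighbors = np.full((n_tet, 4), -1, dtype=np.int64)
    i = 0
    m = len(sorted_key)
    boundary_rows = []
    while i < m:
        j = i + 1
        while j < m and (sorted_key[j] == sorted_key[i]).all():
            j += 1
        rows = order[i:j]
        if j - i == 2:
            t0, l0 = divmod(rows[0], 4)
            t1, l1 = divmod(rows[1], 4)
            neighbors[t0, l0] = t1
            neighbors[t1, l1] = t0
        elif j - i == 1:
            boundary_rows.append(rows[0])
        else:
            t0 = rows[0] // 4
            raise MeshValidationError(
                f"face shared by more than two tets near tet {t0}")
        i = j

    # geometric face data
    fv = vertices[faces]                              # (n_tet, 4, 3, 3)
    cross = np.cross(fv[:, :, 1] - fv[:, :, 0], fv[:, :, 2] - fv[:, :, 0])
    face_area = 0.5 * np.linalg.norm(cross, axis=-1)
    ndx = np.full((n_tet, 4), np.nan)
    has = neighbors >= 0
    ndx[has] = np.linalg.norm(bary[neighbors[has]] - bary[np.nonzero(has)[0]],
                              axis=-1)

    # boundary triangles
    boundary_rows = np.array(sorted(boundary_rows), dtype=np.int64)
    tri_owner = boundary_rows // 4
    tri_local = boundary_rows % 4
    surface_tris = tets[tri_owner][np.arange(len(tri_owner))[:, None],
                                   _FACE_LOCAL[tri_local]]
    tv = vertices[surface_tris]
    tcross = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])
    tri_area = 0.5 * np.linalg.norm(tcross, axis=-1)
    with np.errstate(invalid="ignore"):
        tri_normal = tcross / np.linalg.norm(tcross, axis=-1, keepdims=True)
    tri_bary = tv.mean(axis=1)

    # triangle adjacency across shared edges
    n_tri = len(surface_tris)
    tri_neighbors = np.full((n_tri, 3), -1, dtype=np.int64)
    if n_tri:
        e_local = np.array([[0, 1], [1, 2], [2, 0]])
        edges = np.sort(surface_tris[:, e_local], axis=2).reshape(-1, 2)
        eorder = np.lexsort((edges[:, 1], edges[:, 0]))
        se = edges[eorder]
        i = 0
        while i < len(se):
            j = i + 1
            while j < len(se) and (se[j] == se[i]).all():
                j += 1
            rows = eorder[i:j]
            if j - i == 2:
                t0, l0 = divmod(rows[0], 3)
                t1, l1 = divmod(rows[1], 3)
                tri_neighbors[t0, l0] = t1
                tri_neighbors[t1, l1] = t0
            i = j

    mesh = Mesh(vertices=vertices, tets=tets, surface_tris=surface_tris,
                tri_owner=tri_owner, tet_neighbors=neighbors,
                tet_volume=vol, tet_barycenter=bary, face_area=face_area,
                neighbor_dx=ndx, tri_area=tri_area, tri_barycenter=tri_bary,
                tri_normal=tri_normal, tri_neighbors=tri_neighbors)
    return mesh


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

def load_mesh(path, format: str, scale: float = 1.0) -> Mesh:
    """Load a tetrahedral mesh.

    Parameters
    ----------
    path : str or Path
        ``.msh`` file for ``format="gmsh2"``; the ``.node`` file (or common
        stem) of a TetGen triplet for ``format="tetgen"``.
    format : {"gmsh2", "tetgen"}
    scale : float
        Meters per file unit (e.g. 1e-6 for a mesh drawn in micrometers).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if format == "gmsh2":
        return load_gmsh2(path, scale)
    if format == "tetgen":
        return load_tetgen(path, scale)
    raise ValueError(f"unknown mesh format {format!r}")


def load_gmsh2(path, scale: float = 1.0) -> Mesh:
    path = _FsPath(path)
    lines = path.read_text().splitlines()
    nodes: dict[int, list[float]] = {}
    tets: list[list[int]] = []
    tet_tags: list[int] = []
    tris: list[list[int]] = []
    tri_tags: list[int] = []
    phys_names: dict[tuple[int, int], str] = {}
    i = 0
    n = len(lines)

    def err(lineno, msg):
        return MeshParseError(f"{path.name}:{lineno + 1}: {msg}")

    while i < n:
        ln = lines[i].strip()
        if ln == "$MeshFormat":
            parts = lines[i + 1].split()
            if not parts or not parts[0].startswith("2"):
                raise err(i + 1, f"unsupported Gmsh version {parts[:1]}")
            i += 3
        elif ln == "$PhysicalNames":
            cnt = int(lines[i + 1])
            for j in range(cnt):
                parts = lines[i + 2 + j].split(maxsplit=2)
                if len(parts) < 3:
                    raise err(i + 2 + j, "malformed physical name")
                phys_names[(int(parts[0]), int(parts[1]))] = parts[2].strip('"')
            i += 3 + cnt
        elif ln == "$Nodes":
            try:
                cnt = int(lines[i + 1])
            except (IndexError, ValueError):
                raise err(i + 1, "expected node count")
            for j in range(cnt):
                parts = lines[i + 2 + j].split()
                if len(parts) != 4:
                    raise err(i + 2 + j, "expected 'id x y z'")
                nodes[int(parts[0])] = [float(p) for p in parts[1:]]
            i += 3 + cnt
        elif ln == "$Elements":
            try:
                cnt = int(lines[i + 1])
            except (IndexError, ValueError):
                raise err(i + 1, "expected element count")
            for j in range(cnt):
                parts = lines[i + 2 + j].split()
                try:
                    etype = int(parts[1])
                    ntags = int(parts[2])
                    tags = [int(t) for t in parts[3:3 + ntags]]
                    conn = [int(t) for t in parts[3 + ntags:]]
                except (IndexError, ValueError):
                    raise err(i + 2 + j, "malformed element record")
                phys = tags[0] if tags else 0
                if etype == 4:
                    if len(conn) != 4:
                        raise err(i + 2 + j, "tetrahedron needs 4 nodes")
                    tets.append(conn)
                    tet_tags.append(phys)
                elif etype == 2:
                    if len(conn) != 3:
                        raise err(i + 2 + j, "triangle needs 3 nodes")
                    tris.append(conn)
                    tri_tags.append(phys)
                # other element types (points, lines) are ignored
            i += 3 + cnt
        elif ln.startswith("$End") or not ln:
            i += 1
        elif ln.startswith("$"):
            # skip unknown section
            end = "$End" + ln[1:]
            while i < n and lines[i].strip() != end:
                i += 1
            i += 1
        else:
            raise err(i, f"unexpected content {ln[:40]!r}")

    if not tets:
        raise MeshParseError(f"{path.name}: no tetrahedrons found")
    ids = sorted(nodes)
    remap = {nid: k for k, nid in enumerate(ids)}
    vertices = np.array([nodes[nid] for nid in ids]) * scale
    tet_arr = np.array([[remap[v] for v in t] for t in tets])
    mesh = build_mesh(vertices, tet_arr)

    # physical groups -> compartments / patches
    tet_tags = np.asarray(tet_tags)
    for tag in sorted(set(tet_tags.tolist())):
        if tag == 0 and len(set(tet_tags.tolist())) == 1:
            break
        name = phys_names.get((3, tag), f"comp_{tag}")
        mesh.add_compartment(name, np.flatnonzero(tet_tags == tag))
    if not mesh.compartments:
        mesh.add_compartment("comp")
    if tris:
        # map declared triangles onto the computed surface triangles
        tri_lookup = {}
        for s, t in enumerate(mesh.surface_tris):
            tri_lookup[tuple(sorted(t.tolist()))] = s
        tri_tags_arr = np.asarray(tri_tags)
        for tag in sorted(set(tri_tags_arr.tolist())):
            name = phys_names.get((2, tag), f"patch_{tag}")
            members = []
            for t, tag_t in zip(tris, tri_tags):
                if tag_t != tag:
                    continue
                key = tuple(sorted(remap[v] for v in t))
                if key in tri_lookup:
                    members.append(tri_lookup[key])
            if members:
                mesh.add_patch(name, np.array(sorted(members)),
                               inner=next(iter(mesh.compartments)))
    return mesh


def load_tetgen(path, scale: float = 1.0) -> Mesh:
    path = _FsPath(path)
    stem = path.with_suffix("") if path.suffix in (".node", ".ele", ".face") \
        else path
    node_path = stem.with_suffix(".node")
    ele_path = stem.with_suffix(".ele")
    face_path = stem.with_suffix(".face")

    def rows(p):
        out = []
        for lineno, ln in enumerate(p.read_text().splitlines()):
            ln = ln.split("#", 1)[0].strip()
            if ln:
                out.append((lineno, ln.split()))
        return out

    nrows = rows(node_path)
    try:
        n_nodes = int(nrows[0][1][0])
    except (IndexError, ValueError):
        raise MeshParseError(f"{node_path.name}:1: malformed header")
    ids, coords = [], []
    for lineno, parts in nrows[1:1 + n_nodes]:
        if len(parts) < 4:
            raise MeshParseError(f"{node_path.name}:{lineno + 1}: "
                                 "expected 'id x y z'")
        ids.append(int(parts[0]))
        coords.append([float(x) for x in parts[1:4]])
    remap = {nid: k for k, nid in enumerate(ids)}
    vertices = np.array(coords) * scale

    erows = rows(ele_path)
    try:
        n_ele = int(erows[0][1][0])
    except (IndexError, ValueError):
        raise MeshParseError(f"{ele_path.name}:1: malformed header")
    tets, attrs = [], []
    for lineno, parts in erows[1:1 + n_ele]:
        if len(parts) < 5:
            raise MeshParseError(f"{ele_path.name}:{lineno + 1}: "
                                 "expected 'id n0 n1 n2 n3 [attr]'")
        tets.append([remap[int(v)] for v in parts[1:5]])
        attrs.append(int(float(parts[5])) if len(parts) > 5 else 0)
    mesh = build_mesh(vertices, np.array(tets))
    attrs = np.asarray(attrs)
    for tag in sorted(set(attrs.tolist())):
        if tag == 0 and len(set(attrs.tolist())) == 1:
            mesh.add_compartment("comp")
        else:
            mesh.add_compartment(f"comp_{tag}", np.flatnonzero(attrs == tag))
    if not mesh.compartments:
        mesh.add_compartment("comp")

    if face_path.exists():
        frows = rows(face_path)
        n_face = int(frows[0][1][0])
        tri_lookup = {tuple(sorted(t.tolist())): s
                      for s, t in enumerate(mesh.surface_tris)}
        markers: dict[int, list[int]] = {}
        for lineno, parts in frows[1:1 + n_face]:
            tri = tuple(sorted(remap[int(v)] for v in parts[1:4]))
            marker = int(parts[4]) if len(parts) > 4 else 0
            if tri in tri_lookup:
                markers.setdefault(marker, []).append(tri_lookup[tri])
        for marker, members in sorted(markers.items()):
            mesh.add_patch(f"patch_{marker}", np.array(sorted(members)),
                           inner=next(iter(mesh.compartments)))
    return mesh


def write_gmsh2(mesh: Mesh, path, scale: float = 1.0) -> None:
    """Write Gmsh v2 ASCII. ``scale`` is meters-per-file-unit, matching
    the loader, so a write/load round trip with the same scale is exact."""
    path = _FsPath(path)
    out = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
           str(len(mesh.vertices))]
    for k, v in enumerate(mesh.vertices):
        out.append(f"{k} {float(v[0] / scale)!r} {float(v[1] / scale)!r} "
                   f"{float(v[2] / scale)!r}")
    out.append("$EndNodes")
    out.append("$Elements")
    comp_tag = {name: i + 1 for i, name in enumerate(mesh.compartments)}
    tet_tag = np.ones(mesh.n_tets, dtype=int)
    for name, comp in mesh.compartments.items():
        tet_tag[comp.tets] = comp_tag[name]
    out.append(str(mesh.n_tets))
    for k, t in enumerate(mesh.tets):
        out.append(f"{k} 4 2 {tet_tag[k]} {tet_tag[k]} "
                   f"{t[0]} {t[1]} {t[2]} {t[3]}")
    out.append("$EndElements")
    path.write_text("\n".join(out) + "\n")


def write_tetgen(mesh: Mesh, stem, scale: float = 1.0) -> None:
    stem = _FsPath(stem)
    node = [f"{len(mesh.vertices)} 3 0 0"]
    for k, v in enumerate(mesh.vertices):
        node.append(f"{k} {float(v[0] / scale)!r} {float(v[1] / scale)!r} "
                    f"{float(v[2] / scale)!r}")
    stem.with_suffix(".node").write_text("\n".join(node) + "\n")
    ele = [f"{mesh.n_tets} 4 0"]
    for k, t in enumerate(mesh.tets):
        ele.append(f"{k} {t[0]} {t[1]} {t[2]} {t[3]}")
    stem.with_suffix(".ele").write_text("\n".join(ele) + "\n")


# ---------------------------------------------------------------------------
# synthetic meshes
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def make_sphere_mesh(diameter: float, target_edge: float, seed: int = 0,
                     *, max_nodes: int = 300_000) -> Mesh:
    """Tetrahedralize a ball of the given diameter.

    Surface nodes are placed on a Fibonacci lattice and interior nodes on a
    seeded, jittered cubic grid; the Delaunay triangulation of the union
    fills the (convex) ball.  The achieved mean tet edge tracks
    ``target_edge`` to within ~30%.  Deterministic for a fixed seed.
    """
    if target_edge >= diameter:
        raise ValueError("target_edge must be smaller than diameter")
    r = diameter / 2.0
    h = target_edge * 0.96          # point spacing calibrated to mean edge
    n_surf = max(12, int(round(4 * np.pi * r * r / (h * h * 0.72))))
    if n_surf > max_nodes:
        raise MeshResourceError(
            f"target_edge {target_edge:g} m needs ~{n_surf} surface nodes "
            f"(> budget {max_nodes})")
    rng = np.random.default_rng(seed)
    surf = _fibonacci_sphere(n_surf) * r

    grid = np.arange(-r + h / 2, r, h)
    if len(grid) == 0:
        grid = np.array([0.0])
    gx, gy, gz = np.meshgrid(grid, grid, grid, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    pts = pts + rng.uniform(-0.22 * h, 0.22 * h, size=pts.shape)
    keep = np.linalg.norm(pts, axis=1) < r - 0.55 * h
    interior = pts[keep]
    allpts = np.vstack([surf, interior])
    if len(allpts) > max_nodes:
        raise MeshResourceError(
            f"target_edge {target_edge:g} m needs {len(allpts)} nodes "
            f"(> budget {max_nodes})")
    from scipy.spatial import Delaunay
    tri = Delaunay(allpts)
    tets = tri.simplices
    # drop slivers (degenerate boundary artifacts of the Delaunay hull)
    vol = np.abs(_tet_volumes_signed(allpts, tets))
    tets = tets[vol > 1e-9 * vol.max()]
    # the hull is inscribed in the ball; rescale so the meshed volume
    # matches the analytic ball volume (coarse meshes would otherwise
    # undershoot by the chord-sagitta deficit)
    v_ball = 4.0 / 3.0 * np.pi * r ** 3
    v_mesh = float(np.abs(_tet_volumes_signed(allpts, tets)).sum())
    allpts = allpts * (v_ball / v_mesh) ** (1.0 / 3.0)
    mesh = build_mesh(allpts, tets)
    mesh.add_compartment("comp")
    mesh.add_patch("surf", inner="comp")
    return mesh


def make_box_mesh(lengths, target_edge: float, seed: int = 0,
                  *, max_nodes: int = 300_000) -> Mesh:
    """Tetrahedralized axis-aligned box with one corner at the origin."""
    lengths = np.asarray(lengths, float)
    if np.any(target_edge >= lengths):
        raise ValueError("target_edge must be smaller than every box side")
    h = target_edge * 0.83
    rng = np.random.default_rng(seed)
    axes = []
    for L in lengths:
        n = max(2, int(round(L / h)) + 1)
        axes.append(np.linspace(0, L, n))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    if len(pts) > max_nodes:
        raise MeshResourceError(f"{len(pts)} nodes exceed budget {max_nodes}")
    jitter = rng.uniform(-0.2 * h, 0.2 * h, size=pts.shape)
    on_face = (np.isclose(pts, 0.0) |
               np.isclose(pts, lengths[None, :]))
    jitter[on_face] = 0.0
    pts = pts + jitter
    from scipy.spatial import Delaunay
    tri = Delaunay(pts)
    tets = tri.simplices
    vol = np.abs(_tet_volumes_signed(pts, tets))
    tets = tets[vol > 1e-9 * vol.max()]
    mesh = build_mesh(pts, tets)
    mesh.add_compartment("comp")
    mesh.add_patch("surf", inner="comp")
    return mesh


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

_EDGE_LOCAL = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])


def tet_edge_means(mesh: Mesh) -> np.ndarray:
    """Mean of the 6 edge lengths of every tet (the 'size' convention)."""
    ev = mesh.vertices[mesh.tets[:, _EDGE_LOCAL]]     # (n, 6, 2, 3)
    return np.linalg.norm(ev[:, :, 1] - ev[:, :, 0], axis=-1).mean(axis=1)


def mesh_stats(mesh: Mesh, bins: int = 30) -> MeshStats:
    edge_mean = tet_edge_means(mesh)
    counts, edges = np.histogram(edge_mean, bins=bins)
    return MeshStats(edge_mean=edge_mean, hist_counts=counts, hist_edges=edges)
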