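"""Synthetic atrial geometry, voxelization, fibers and electrode placement.

Coordinates are millimetres throughout, right-handed. The synthetic chamber
is a star-shaped ellipsoid-like closed surface with an appendage bulge and
three circular holes (superior/inferior vena cava, tricuspid valve) cut and
rim-labeled. The thin myocardial wall lies on the *outward* side of this
endocardial surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "TriSurface",
    "VoxelLattice",
    "FiberField",
    "ZoneSpec",
    "ElectrodeArray",
    "BalloonArray",
    "SurfaceSampler",
    "make_synthetic_atrium",
    "close_holes",
    "voxelize_shell",
    "assign_fibers",
    "place_plaques",
    "place_balloon",
    "surface_point",
    "DEFAULT_HOLES",
    "DEFAULT_REGIONS",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TriSurface:
    """Triangulated (endocardial) surface with per-node anatomical labels.

    ``labels`` maps a tag such as ``"free-wall"``, ``"appendage"``,
    ``"SVC-rim"``, ``"SAN"`` ... to an array of node indices.  Every node
    carries at least the default ``"free-wall"`` tag unless overridden.
    """

    nodes: np.ndarray          # (N, 3) float
    triangles: np.ndarray      # (M, 3) int
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    closed: bool = True

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (M, 3)")
        areas = 0.5 * np.linalg.norm(
            np.cross(
                self.nodes[self.triangles[:, 1]] - self.nodes[self.triangles[:, 0]],
                self.nodes[self.triangles[:, 2]] - self.nodes[self.triangles[:, 0]],
            ),
            axis=1,
        )
        if np.any(areas <= 1e-12):
            raise ValueError("degenerate (zero-area) triangle in surface")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.nodes, faces=self.triangles, process=False
        )

    def label_of(self, tag: str) -> np.ndarray:
        """Node indices carrying ``tag`` (empty array if absent)."""
        return np.asarray(self.labels.get(tag, np.empty(0, dtype=np.int64)))

    def boundary_loops(self) -> list[np.ndarray]:
        """Closed polylines of boundary nodes, one per hole (empty if closed)."""
        edges = {}
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                edges[key] = edges.get(key, 0) + 1
        boundary = [e for e, c in edges.items() if c == 1]
        if not boundary:
            return []
        nxt: dict[int, list[int]] = {}
        for a, b in boundary:
            nxt.setdefault(a, []).append(b)
            nxt.setdefault(b, []).append(a)
        loops, seen = [], set()
        for start in nxt:
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur, prev = start, -1
            while True:
                cands = [v for v in nxt[cur] if v != prev]
                if not cands:
                    break
                prev, cur = cur, cands[0]
                if cur == start:
                    break
                loop.append(cur)
                seen.add(cur)
            loops.append(np.asarray(loop, dtype=np.int64))
        return loops

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit)."""
        vn = np.asarray(self.as_trimesh().vertex_normals, dtype=float)
        n = np.linalg.norm(vn, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return vn / n

    def check_edge_manifold(self) -> None:
        """Raise if a closed surface has edges not shared by exactly 2 faces."""
        edges = {}
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                edges[key] = edges.get(key, 0) + 1
        counts = np.array(list(edges.values()))
        if self.closed and not np.all(counts == 2):
            raise ValueError("non-manifold closed surface")
        if not self.closed and np.any(counts > 2):
            raise ValueError("non-manifold surface")

    # -- I/O ---------------------------------------------------------------
    def save(self, path: str | Path, file_type: str | None = None) -> None:
        """Write PLY/OFF geometry plus a JSON label sidecar."""
        path = Path(path)
        self.as_trimesh().export(path, file_type=file_type)
        sidecar = path.with_suffix(path.suffix + ".labels.json")
        payload = {
            "closed": self.closed,
            "labels": {k: np.asarray(v).tolist() for k, v in self.labels.items()},
        }
        sidecar.write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TriSurface":
        path = Path(path)
        mesh = trimesh.load(path, process=False)
        sidecar = path.with_suffix(path.suffix + ".labels.json")
        labels, closed = {}, bool(mesh.is_watertight)
        if sidecar.exists():
            payload = json.loads(sidecar.read_text())
            labels = {
                k: np.asarray(v, dtype=np.int64)
                for k, v in payload["labels"].items()
            }
            closed = bool(payload["closed"])
        return cls(
            nodes=np.asarray(mesh.vertices, dtype=float),
            triangles=np.asarray(mesh.faces, dtype=np.int64),
            labels=labels,
            closed=closed,
        )


@dataclass
class VoxelLattice:
    """Thin-walled cubic computational mesh.

    Voxel centers sit at ``origin + (ijk + 0.5) * h``.  ``index_grid`` maps a
    dense (nx, ny, nz) block to the flat myocardial voxel index (-1 outside
    the wall).  ``nearest_node`` links each voxel to the closest endocardial
    surface node; ``normal`` and ``depth`` are the outward surface normal and
    the distance from the endocardium at the voxel center.
    """

    h: float
    thickness: float
    origin: np.ndarray           # (3,)
    ijk: np.ndarray              # (K, 3) int
    index_grid: np.ndarray       # (nx, ny, nz) int
    nearest_node: np.ndarray     # (K,) int
    normal: np.ndarray           # (K, 3)
    depth: np.ndarray            # (K,)

    @property
    def n_voxels(self) -> int:
        return len(self.ijk)

    @property
    def centers(self) -> np.ndarray:
        return self.origin + (self.ijk + 0.5) * self.h

    def neighbor_table(self) -> np.ndarray:
        """(K, 6) flat indices of the -x,+x,-y,+y,-z,+z face neighbors (-1 = wall)."""
        nx, ny, nz = self.index_grid.shape
        out = np.full((self.n_voxels, 6), -1, dtype=np.int64)
        offs = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
        for a, (di, dj, dk) in enumerate(offs):
            p = self.ijk + np.array([di, dj, dk])
            ok = (
                (p[:, 0] >= 0) & (p[:, 0] < nx)
                & (p[:, 1] >= 0) & (p[:, 1] < ny)
                & (p[:, 2] >= 0) & (p[:, 2] < nz)
            )
            out[ok, a] = self.index_grid[p[ok, 0], p[ok, 1], p[ok, 2]]
        return out

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["h"] = self.h
            f.attrs["thickness"] = self.thickness
            f.create_dataset("origin", data=self.origin)
            f.create_dataset("ijk", data=self.ijk)
            f.create_dataset("index_grid", data=self.index_grid)
            f.create_dataset("nearest_node", data=self.nearest_node)
            f.create_dataset("normal", data=self.normal)
            f.create_dataset("depth", data=self.depth)

    @classmethod
    def load(cls, path: str | Path) -> "VoxelLattice":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                h=float(f.attrs["h"]),
                thickness=float(f.attrs["thickness"]),
                origin=f["origin"][:],
                ijk=f["ijk"][:],
                index_grid=f["index_grid"][:],
                nearest_node=f["nearest_node"][:],
                normal=f["normal"][:],
                depth=f["depth"][:],
            )


@dataclass
class FiberField:
    """Per-voxel unit fiber direction, tangent to the wall."""

    vectors: np.ndarray  # (K, 3)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms < 1e-9):
            raise ValueError("zero-norm fiber vector")


@dataclass
class ZoneSpec:
    """Circular membrane-heterogeneity zone (elevated ACh concentration)."""

    center: np.ndarray   # (3,) mm, on the myocardium
    radius: float        # mm
    ach: float = 0.03    # µM

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("zone radius must be positive")


@dataclass
class ElectrodeArray:
    """Epicardial plaque electrodes: positions plus grid topology."""

    positions: np.ndarray               # (n, 3)
    plaque_id: np.ndarray               # (n,) int, which plaque
    grid_index: np.ndarray              # (n, 2) int, (row, col) within plaque
    plaque_shapes: list[tuple[int, int]]
    control_points: list[np.ndarray]    # 3 points per plaque

    @property
    def n_channels(self) -> int:
        return len(self.positions)


@dataclass
class BalloonArray:
    """64-electrode noncontact balloon: 8 splines x 8 rings, strictly interior."""

    positions: np.ndarray  # (64, 3)
    center: np.ndarray     # (3,)
    radius: float          # mean radius, mm


# ---------------------------------------------------------------------------
# surface sampling helper
# ---------------------------------------------------------------------------

class SurfaceSampler:
    """Dense point sampling of a triangulated surface for proximity queries.

    Each triangle is covered by a barycentric grid with spacing <= ``spacing``;
    queries return the nearest sample, an interpolated outward normal and the
    nearest surface node.  Accuracy of distances is O(spacing).
    """

    def __init__(self, surface: TriSurface, spacing: float = 0.25):
        self.surface = surface
        verts = surface.nodes
        tris = surface.triangles
        vnorm = surface.vertex_normals()
        pts, nrm, node = [], [], []
        for tri in tris:
            p0, p1, p2 = verts[tri]
            edge = max(
                np.linalg.norm(p1 - p0),
                np.linalg.norm(p2 - p0),
                np.linalg.norm(p2 - p1),
            )
            n = max(1, int(np.ceil(edge / spacing)))
            for i in range(n + 1):
                for j in range(n + 1 - i):
                    a, b = i / n, j / n
                    c = 1.0 - a - b
                    w = np.array([c, a, b])
                    pts.append(w @ verts[tri])
                    v = w @ vnorm[tri]
                    nrm.append(v / max(np.linalg.norm(v), 1e-12))
                    node.append(tri[int(np.argmax(w))])
        self.points = np.asarray(pts)
        self.normals = np.asarray(nrm)
        self.node_index = np.asarray(node, dtype=np.int64)
        self.tree = cKDTree(self.points)

    def nearest(self, points: np.ndarray):
        """Return (distance, sample point, normal, surface node index)."""
        d, idx = self.tree.query(np.atleast_2d(points))
        return d, self.points[idx], self.normals[idx], self.node_index[idx]


# ---------------------------------------------------------------------------
# synthetic atrium
# ---------------------------------------------------------------------------

DEFAULT_HOLES: dict[str, dict] = {
    "SVC": {"direction": (0.15, 0.20, 1.00), "radius": 5.0},
    "IVC": {"direction": (0.10, -0.25, -1.00), "radius": 5.0},
    "valve": {"direction": (-1.00, 0.15, -0.35), "radius": 8.0},
}

DEFAULT_REGIONS: dict[str, dict] = {
    # SAN: sino-atrial node region, anterolateral below the SVC ostium
    "SAN": {"direction": (0.55, -0.30, 0.75), "radius": 4.0},
    # RAGP: ganglionated-plexus fat pad at the SVC-atrial junction
    "RAGP": {"direction": (0.65, 0.20, 0.65), "radius": 5.0},
    # IA: interatrial (Bachmann) bundle region, anterosuperior
    "IA": {"direction": (0.10, 0.75, 0.60), "radius": 5.0},
    # CS: coronary-sinus ostium region, inferoseptal
    "CS": {"direction": (-0.45, -0.80, -0.50), "radius": 4.0},
}

_APPENDAGE_DIR = np.array([0.55, 0.70, 0.45])
_APPENDAGE_SIGMA = 0.45   # radians
_APPENDAGE_AMP = 0.22     # fractional radial bulge


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _radial_shape(dirs: np.ndarray, semi_axes, appendage_amp: float) -> np.ndarray:
    """Star-shaped radius R(direction): ellipsoid plus a Gaussian bulge."""
    a, b, c = semi_axes
    base = 1.0 / np.sqrt(
        (dirs[:, 0] / a) ** 2 + (dirs[:, 1] / b) ** 2 + (dirs[:, 2] / c) ** 2
    )
    if appendage_amp > 0:
        cosang = np.clip(dirs @ _unit(_APPENDAGE_DIR), -1, 1)
        ang = np.arccos(cosang)
        base = base * (1.0 + appendage_amp * np.exp(-(ang / _APPENDAGE_SIGMA) ** 2))
    return base


def make_synthetic_atrium(
    semi_axes: tuple[float, float, float] = (18.0, 16.0, 15.0),
    subdivisions: int = 3,
    holes: dict[str, dict] | None = DEFAULT_HOLES,
    regions: dict[str, dict] | None = None,
    appendage_amp: float = _APPENDAGE_AMP,
    jitter: float = 0.1,
    seed: int = 0,
) -> TriSurface:
    """Generate the synthetic right-atrial endocardial surface.

    An icosphere is mapped onto an ellipsoid-like star-shaped chamber
    (semi-axes in mm) with a labeled appendage bulge, a smooth seeded radial
    jitter, circular holes cut for the named rims, and angular anatomical
    regions labeled (SAN, RAGP, IA, CS).  Pass ``holes=None`` for a closed
    chamber (e.g. a plain sphere fixture with ``appendage_amp=0``).
    """
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = np.asarray(ico.vertices, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    tris = np.asarray(ico.faces, dtype=np.int64)

    radii = _radial_shape(dirs, semi_axes, appendage_amp)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        bump = rng.normal(0.0, 1.0, len(dirs))
        # smooth the jitter over the 1-ring so the surface stays gentle
        adj = [[] for _ in range(len(dirs))]
        for t in tris:
            for u, v in ((0, 1), (1, 2), (2, 0)):
                adj[t[u]].append(t[v])
                adj[t[v]].append(t[u])
        for _ in range(3):
            bump = np.array([(bump[i] + bump[a].mean()) / 2 if (a := np.array(adj[i])).size else bump[i] for i in range(len(dirs))])
        radii = radii + jitter * bump

    nodes = dirs * radii[:, None]
    labels: dict[str, np.ndarray] = {}

    if appendage_amp > 0:
        cosang = np.clip(dirs @ _unit(_APPENDAGE_DIR), -1, 1)
        labels["appendage"] = np.where(np.arccos(cosang) < 1.2 * _APPENDAGE_SIGMA)[0]

    if holes:
        keep = np.ones(len(nodes), dtype=bool)
        hole_dirs = {}
        for name, spec in holes.items():
            d = _unit(spec["direction"])
            hole_dirs[name] = d
            ang_rad = spec["radius"] / float(np.mean(semi_axes))
            ang = np.arccos(np.clip(dirs @ d, -1, 1))
            keep &= ang > ang_rad
        remap = -np.ones(len(nodes), dtype=np.int64)
        remap[keep] = np.arange(keep.sum())
        tri_keep = keep[tris].all(axis=1)
        new_tris = remap[tris[tri_keep]]
        new_nodes = nodes[keep]
        new_dirs = dirs[keep]
        labels = {
            k: remap[v][remap[v] >= 0] for k, v in labels.items()
        }
        surf = TriSurface(new_nodes, new_tris, labels, closed=False)
        loops = surf.boundary_loops()
        if len(loops) != len(holes):
            raise ValueError(
                f"hole cutting produced {len(loops)} boundary loops, "
                f"expected {len(holes)} (non-manifold output)"
            )
        for loop in loops:
            cen_dir = _unit(new_dirs[loop].mean(axis=0))
            name = max(hole_dirs, key=lambda n: hole_dirs[n] @ cen_dir)
            surf.labels[f"{name}-rim"] = loop
        dirs = new_dirs
    else:
        surf = TriSurface(nodes, tris, labels, closed=True)

    for name, spec in (regions if regions is not None else DEFAULT_REGIONS).items():
        d = _unit(spec["direction"])
        ang_rad = spec["radius"] / float(np.mean(semi_axes))
        ang = np.arccos(np.clip(dirs @ d, -1, 1))
        idx = np.where(ang < ang_rad)[0]
        if idx.size:
            surf.labels[name] = idx

    tagged = set()
    for v in surf.labels.values():
        tagged.update(np.asarray(v).tolist())
    surf.labels["free-wall"] = np.array(
        sorted(set(range(surf.n_nodes)) - tagged), dtype=np.int64
    )
    surf.check_edge_manifold()
    return surf


def close_holes(surface: TriSurface) -> TriSurface:
    """Fan-fill every boundary loop to produce the closed inverse-problem surface.

    Each rim loop gains a center vertex at its centroid; cap orientation
    follows the surrounding mesh so outward normals stay consistent.
    """
    loops = surface.boundary_loops()
    if not loops:
        return TriSurface(
            surface.nodes.copy(), surface.triangles.copy(),
            {k: v.copy() for k, v in surface.labels.items()}, closed=True,
        )
    # directed boundary edges as they appear in triangles (a -> b)
    directed = set()
    for tri in surface.triangles:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            directed.add((a, b))
    nodes = [surface.nodes]
    tris = [surface.triangles]
    labels = {k: v.copy() for k, v in surface.labels.items()}
    next_idx = surface.n_nodes
    for loop in loops:
        center = surface.nodes[loop].mean(axis=0)
        nodes.append(center[None, :])
        cap = []
        m = len(loop)
        for i in range(m):
            a, b = int(loop[i]), int(loop[(i + 1) % m])
            # mesh triangle holds edge a->b or b->a exactly once on the rim;
            # the cap triangle takes the opposite direction
            if (a, b) in directed:
                cap.append([b, a, next_idx])
            else:
                cap.append([a, b, next_idx])
        tris.append(np.asarray(cap, dtype=np.int64))
        labels.setdefault("hole-cap", np.empty(0, dtype=np.int64))
        labels["hole-cap"] = np.concatenate(
            [labels["hole-cap"], np.array([next_idx], dtype=np.int64)]
        )
        next_idx += 1
    out = TriSurface(
        np.vstack(nodes), np.vstack(tris), labels, closed=True
    )
    out.check_edge_manifold()
    return out


def surface_point(surface: TriSurface, direction, center=None) -> np.ndarray:
    """Surface node closest to the ray from the chamber center along ``direction``."""
    c = surface.nodes.mean(axis=0) if center is None else np.asarray(center)
    d = _unit(direction)
    rel = surface.nodes - c
    proj = rel @ d
    perp = np.linalg.norm(rel - proj[:, None] * d, axis=1)
    score = np.where(proj > 0, perp, np.inf)
    return surface.nodes[int(np.argmin(score))]


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxelize_shell(
    surface: TriSurface,
    thickness: float = 1.75,
    h: float = 0.25,
    sampler: SurfaceSampler | None = None,
    keep_largest: bool = True,
) -> VoxelLattice:
    """Voxelize the thin myocardial wall outside the endocardial surface.

    A voxel belongs to the wall when its center lies within ``[0, thickness]``
    of the surface along the outward normal of the nearest surface sample and
    within a small tangential tolerance (which caps the wall at hole rims).
    Voxel centers sit on the global lattice ``(i + 1/2) h``.
    """
    if thickness < 2 * h:
        raise ValueError("wall thickness below 2 h: wall unresolvable")
    sampler = sampler or SurfaceSampler(surface, spacing=min(0.5 * h, 0.5))

    lo = surface.nodes.min(axis=0) - (thickness + 2 * h)
    hi = surface.nodes.max(axis=0) + (thickness + 2 * h)
    i0 = np.floor(lo / h).astype(np.int64)
    i1 = np.ceil(hi / h).astype(np.int64)
    origin = i0 * h
    shape = tuple((i1 - i0).tolist())

    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij",
    )
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    centers = origin + (ijk + 0.5) * h

    # coarse prefilter on distance to the node cloud to keep KD queries cheap
    node_tree = cKDTree(surface.nodes)
    dmax_tri = 0.0
    tri = surface.triangles
    for a, b in ((0, 1), (1, 2), (2, 0)):
        dmax_tri = max(
            dmax_tri,
            float(np.linalg.norm(
                surface.nodes[tri[:, a]] - surface.nodes[tri[:, b]], axis=1
            ).max()),
        )
    coarse, _ = node_tree.query(centers)
    cand = coarse <= thickness + dmax_tri
    ijk, centers = ijk[cand], centers[cand]

    dist, spts, snrm, snode = sampler.nearest(centers)
    rel = centers - spts
    d_n = np.einsum("ij,ij->i", rel, snrm)
    tang2 = np.maximum(dist**2 - d_n**2, 0.0)
    eps = 1e-9
    inside = (d_n >= -eps) & (d_n <= thickness + eps) & (tang2 <= (0.75 * h) ** 2)

    ijk = ijk[inside]
    if keep_largest and len(ijk):
        dense = np.zeros(shape, dtype=bool)
        dense[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
        lab, n = ndimage.label(dense)
        if n > 1:
            counts = np.bincount(lab.ravel())[1:]
            main = 1 + int(np.argmax(counts))
            keep = lab[ijk[:, 0], ijk[:, 1], ijk[:, 2]] == main
            ijk = ijk[keep]
    # recompute per-voxel metadata for the surviving set
    centers = origin + (ijk + 0.5) * h
    dist, spts, snrm, snode = sampler.nearest(centers)
    d_n = np.einsum("ij,ij->i", centers - spts, snrm)

    index_grid = np.full(shape, -1, dtype=np.int64)
    index_grid[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = np.arange(len(ijk))
    return VoxelLattice(
        h=h, thickness=thickness, origin=origin.astype(float),
        ijk=ijk.astype(np.int64), index_grid=index_grid,
        nearest_node=snode.astype(np.int64), normal=snrm, depth=d_n,
    )


# ---------------------------------------------------------------------------
# fibers
# ---------------------------------------------------------------------------

def bar_lattice(shape: tuple[int, int, int], h: float = 0.25) -> VoxelLattice:
    """Rectangular slab lattice (nx, ny, nz voxels) for strip/slab fixtures.

    Surface metadata points at a virtual plane underneath the slab (normal
    +z), so fiber rules and electrogram bookkeeping stay usable.
    """
    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(np.int64)
    index_grid = np.full(shape, -1, dtype=np.int64)
    index_grid[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = np.arange(len(ijk))
    normal = np.tile(np.array([0.0, 0.0, 1.0]), (len(ijk), 1))
    return VoxelLattice(
        h=h, thickness=nz * h, origin=np.zeros(3), ijk=ijk,
        index_grid=index_grid,
        nearest_node=np.zeros(len(ijk), dtype=np.int64),
        normal=normal, depth=(ijk[:, 2] + 0.5) * h,
    )


def assign_fibers(
    lattice: VoxelLattice,
    rule: str = "circumferential",
    axis=(0.0, 0.0, 1.0),
) -> FiberField:
    """Rule-based fiber directions, tangent to the wall.

    The default rule wraps fibers circumferentially around the SVC-IVC
    (z) axis, then projects onto the local wall tangent plane.  Near the
    poles of the rule (where the circumferential direction degenerates) an
    arbitrary tangent is substituted.
    """
    if rule != "circumferential":
        raise ValueError(f"unknown fiber rule: {rule}")
    ax = _unit(axis)
    x = lattice.centers - lattice.centers.mean(axis=0)
    f = np.cross(np.broadcast_to(ax, x.shape), x)
    n = lattice.normal
    f = f - np.einsum("ij,ij->i", f, n)[:, None] * n
    norms = np.linalg.norm(f, axis=1)
    bad = norms < 1e-6
    if np.any(bad):
        # fall back to any tangent direction
        alt = np.cross(n[bad], np.array([1.0, 0.0, 0.0]))
        alt_n = np.linalg.norm(alt, axis=1)
        fix = alt_n < 1e-6
        alt[fix] = np.cross(n[bad][fix], np.array([0.0, 1.0, 0.0]))
        f[bad] = alt
        norms = np.linalg.norm(f, axis=1)
    return FiberField(f / norms[:, None])


# ---------------------------------------------------------------------------
# electrode arrays
# ---------------------------------------------------------------------------

# default plaque layouts: free wall 8x10 grid minus one corner (79 ch),
# Bachmann/appendage 4x6 grid (24 ch) -> 103 channels total
DEFAULT_PLAQUE_SHAPES: list[tuple[int, int]] = [(8, 10), (4, 6)]
DEFAULT_PLAQUE_OMIT: list[list[tuple[int, int]]] = [[(7, 9)], []]


def _grid_from_control_points(
    shape: tuple[int, int],
    control_idx: list[tuple[int, int]],
    control_pos: list[np.ndarray],
) -> np.ndarray:
    """Interpolate a full (rows x cols) grid from 3 (index, position) pairs."""
    (i0, j0), (i1, j1), (i2, j2) = control_idx
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in control_pos)
    A = np.array([[i1 - i0, j1 - j0], [i2 - i0, j2 - j0]], dtype=float)
    if abs(np.linalg.det(A)) < 1e-9:
        raise ValueError("degenerate (collinear) control points")
    rhs = np.vstack([p1 - p0, p2 - p0])
    axes = np.linalg.solve(A, rhs)          # rows: row-step and col-step vectors
    if np.linalg.norm(np.cross(axes[0], axes[1])) < 1e-9:
        raise ValueError("degenerate (collinear) control points")
    rows, cols = shape
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rel = np.stack([ii - i0, jj - j0], axis=-1).reshape(-1, 2).astype(float)
    return p0 + rel @ axes


def place_plaques(
    surface: TriSurface,
    control_points: list[list[np.ndarray]],
    control_indices: list[list[tuple[int, int]]] | None = None,
    plaque_shapes: list[tuple[int, int]] | None = None,
    omit: list[list[tuple[int, int]]] | None = None,
    wall_thickness: float = 1.75,
    sampler: SurfaceSampler | None = None,
    project: bool = True,
) -> ElectrodeArray:
    """Build plaque electrode grids from 3 control points each and project them
    onto the epicardial surface (endocardium offset outward by the wall
    thickness).

    ``control_points`` holds, per plaque, the two extremity electrodes and the
    center electrode; ``control_indices`` gives their (row, col) grid slots
    (default: first-row corners and grid center).
    """
    plaque_shapes = plaque_shapes or DEFAULT_PLAQUE_SHAPES
    omit = omit if omit is not None else DEFAULT_PLAQUE_OMIT[: len(plaque_shapes)]
    if project:
        sampler = sampler or SurfaceSampler(surface, spacing=0.5)
    positions, plaque_id, grid_index = [], [], []
    for p, shape in enumerate(plaque_shapes):
        rows, cols = shape
        # default: the two extremities of the first row plus the grid
        # center -- well-conditioned in index space, unlike e.g. two
        # opposite corners with the center (nearly collinear indices)
        cidx = (
            control_indices[p]
            if control_indices is not None
            else [(0, 0), (0, cols - 1), (rows // 2, cols // 2)]
        )
        grid = _grid_from_control_points(shape, cidx, control_points[p])
        if project:
            _, spts, snrm, _ = sampler.nearest(grid)
            grid = spts + wall_thickness * snrm
        skip = set(omit[p]) if p < len(omit) else set()
        k = 0
        for i in range(rows):
            for j in range(cols):
                if (i, j) in skip:
                    k += 1
                    continue
                positions.append(grid[k])
                plaque_id.append(p)
                grid_index.append((i, j))
                k += 1
    return ElectrodeArray(
        positions=np.asarray(positions, dtype=float),
        plaque_id=np.asarray(plaque_id, dtype=np.int64),
        grid_index=np.asarray(grid_index, dtype=np.int64),
        plaque_shapes=list(plaque_shapes),
        control_points=[list(map(np.asarray, cp)) for cp in control_points],
    )


def default_plaque_control_points(
    surface: TriSurface,
    wall_thickness: float = 1.75,
    spacing: float = 2.5,
    sampler: SurfaceSampler | None = None,
) -> list[list[np.ndarray]]:
    """Control points for the two default plaques on the synthetic atrium.

    Plaque 0 (79 ch, 8x10 grid) covers the right free wall; plaque 1
    (24 ch, 4x6) sits between the appendage base and the interatrial
    (Bachmann) region.  For each plaque the three control points (first-row
    extremities and grid center) are laid out in the local tangent plane at
    the plaque center with regular ``spacing`` and projected onto the
    epicardium.
    """
    c = surface.nodes.mean(axis=0)
    sampler = sampler or SurfaceSampler(surface, spacing=0.5)

    def epi_project(pts):
        _, s, n, _ = sampler.nearest(np.atleast_2d(pts))
        return s + wall_thickness * n

    def frame_points(center_dir, up_hint, shape):
        rows, cols = shape
        p0 = surface_point(surface, center_dir, center=c)
        p0 = epi_project(p0)[0]
        _, _, n, _ = sampler.nearest(p0[None, :])
        nrm = n[0]
        u = np.asarray(up_hint, dtype=float)
        u = u - (u @ nrm) * nrm
        u /= np.linalg.norm(u)              # column direction
        v = np.cross(nrm, u)                 # row direction
        ctr_idx = (rows // 2, cols // 2)
        a = p0 - ctr_idx[1] * spacing * u - ctr_idx[0] * spacing * v
        b = a + (cols - 1) * spacing * u
        pts = epi_project(np.vstack([a, b, p0]))
        return [pts[0], pts[1], pts[2]]

    plaque0 = frame_points((1.0, 0.0, -0.05), (0.1, 0.3, -1.0), (8, 10))
    plaque1 = frame_points((-0.05, 1.0, 0.1), (-1.0, 0.0, -0.3), (4, 6))
    return [plaque0, plaque1]


def place_balloon(
    surface: TriSurface,
    center=None,
    radius: float | tuple[float, float, float] = None,
) -> BalloonArray:
    """Place the 64-electrode (8 splines x 8 rings) ellipsoidal balloon array.

    All electrodes must be strictly interior to the closed surface; placement
    refuses otherwise.
    """
    closed = surface if surface.closed else close_holes(surface)
    c = np.asarray(center if center is not None else closed.nodes.mean(axis=0),
                   dtype=float)
    if radius is None:
        extent = (closed.nodes - c)
        radius = 0.45 * float(np.median(np.linalg.norm(extent, axis=1)))
    radii = np.broadcast_to(np.asarray(radius, dtype=float), (3,)).copy()
    if np.isscalar(radius) or radii.ndim == 0:
        radii = np.array([radius, radius, 1.25 * radius], dtype=float)

    thetas = (np.arange(8) + 0.5) / 8 * np.pi
    phis = np.arange(8) / 8 * 2 * np.pi
    pts = []
    for t in thetas:
        for p in phis:
            d = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
            pts.append(c + radii * d)
    pts = np.asarray(pts)
    from .kernels import winding_number

    inside = winding_number(closed.nodes, closed.triangles, pts) > 0.5
    if not np.all(inside):
        raise ValueError(
            f"{int((~inside).sum())} balloon electrodes fall outside the surface"
        )
    return BalloonArray(positions=pts, center=c, radius=float(np.mean(radii)))
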