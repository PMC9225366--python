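"""Triangle-mesh data model, PLY/OBJ I/O, geometry derivations and marker detection.

The pipeline tracks a *template* mesh across a sequence of noisy target scans,
so every stage consumes the same unit: a :class:`SurfaceMesh` with vertices in
millimetres, 0-based triangle indices, and optional per-vertex RGB colors in
[0, 1].  Painted dot markers (high color contrast against their one-ring
neighbourhood) provide sparse texture correspondence for registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


class MeshFormatError(ValueError):
    """Raised when a mesh file does not parse as the named format."""


@dataclass
class SurfaceMesh:
    """A triangle mesh with optional per-vertex color.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex positions in millimetres.
    triangles : (M, 3) int array
        0-based vertex index triples.
    colors : (N, 3) float array, optional
        Per-vertex RGB in [0, 1].
    """

    vertices: np.ndarray
    triangles: np.ndarray
    colors: np.ndarray | None = None
    _normals: np.ndarray | None = field(default=None, repr=False, compare=False)
    _one_ring: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (N, 3) array")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            bad = self.triangles[
                (self.triangles < 0).any(axis=1)
                | (self.triangles >= len(self.vertices)).any(axis=1)
            ][0]
            raise MeshFormatError(f"triangle {bad.tolist()} references out-of-range vertex")
        if self.colors is not None:
            self.colors = np.ascontiguousarray(self.colors, dtype=np.float64)
            if self.colors.shape != (len(self.vertices), 3):
                raise MeshFormatError("colors must be (N, 3)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def normals(self) -> np.ndarray:
        """Per-vertex unit normals (computed lazily, cached)."""
        if self._normals is None:
            self._normals = vertex_normals(self)
        return self._normals

    def one_ring(self) -> list[np.ndarray]:
        """Sorted one-ring vertex neighbourhood for every vertex."""
        if self._one_ring is None:
            nbrs: list[set] = [set() for _ in range(self.n_vertices)]
            for a, b, c in self.triangles:
                nbrs[a].update((b, c))
                nbrs[b].update((a, c))
                nbrs[c].update((a, b))
            self._one_ring = [np.array(sorted(s), dtype=np.int64) for s in nbrs]
        return self._one_ring

    def mean_edge_length(self) -> float:
        tri = self.vertices[self.triangles]
        e = np.concatenate(
            [tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2]]
        )
        return float(np.linalg.norm(e, axis=1).mean())

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """Copy of this mesh with replaced vertex positions (same topology/colors)."""
        return SurfaceMesh(np.asarray(vertices, float), self.triangles.copy(),
                           None if self.colors is None else self.colors.copy())

    def save(self, path) -> None:
        save_mesh(self, path)


@dataclass
class MarkerSet:
    """Detected dot markers: vertex indices and their 3D positions (mm)."""

    vertex_indices: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        if len(np.unique(self.vertex_indices)) != len(self.vertex_indices):
            raise ValueError("marker vertex indices must be unique")

    def __len__(self) -> int:
        return len(self.vertex_indices)


def load_mesh(path, file_format: str | None = None) -> SurfaceMesh:
    """Load a PLY or OBJ mesh, preserving vertex order and per-vertex color.

    Colors are returned in [0, 1]; absent if the file has none.
    """
    import os
    if not os.path.exists(str(path)):
        raise FileNotFoundError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), file_type=file_format,
                          process=False, maintain_order=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - trimesh raises many parse errors
        raise MeshFormatError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh):
        raise MeshFormatError(f"{path} did not contain a single triangle mesh")
    colors = None
    vc = tm.visual.vertex_colors if tm.visual.kind == "vertex" else None
    if vc is not None and len(vc) == len(tm.vertices):
        colors = np.asarray(vc, dtype=np.float64)[:, :3] / 255.0
    return SurfaceMesh(np.asarray(tm.vertices, float),
                       np.asarray(tm.faces, np.int64), colors)


def save_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a mesh as ASCII PLY (with uchar vertex color if present) or OBJ."""
    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    if mesh.colors is not None:
        rgba = np.empty((mesh.n_vertices, 4), dtype=np.uint8)
        rgba[:, :3] = np.clip(np.round(mesh.colors * 255.0), 0, 255).astype(np.uint8)
        rgba[:, 3] = 255
        tm.visual.vertex_colors = rgba
    path = str(path)
    if path.lower().endswith(".ply"):
        with open(path, "wb") as fh:
            fh.write(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))
    else:
        tm.export(path)


def triangle_normals_areas(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Unit face normals (from winding) and face areas."""
    tri = mesh.vertices[mesh.triangles]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    twice_area = np.linalg.norm(cross, axis=1)
    n = np.zeros_like(cross)
    ok = twice_area > 0
    n[ok] = cross[ok] / twice_area[ok, None]
    return n, 0.5 * twice_area


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted per-vertex unit normals.

    Orientation follows triangle winding.  Isolated vertices (no incident
    triangle) get a zero normal; downstream energy terms skip them.
    """
    if len(mesh.triangles) < 1:
        raise ValueError("mesh must have at least one triangle")
    face_n, area = triangle_normals_areas(mesh)
    acc = np.zeros_like(mesh.vertices)
    w = face_n * area[:, None]
    for k in range(3):
        np.add.at(acc, mesh.triangles[:, k], w)
    norm = np.linalg.norm(acc, axis=1)
    out = np.zeros_like(acc)
    ok = norm > 1e-300
    out[ok] = acc[ok] / norm[ok, None]
    return out


def detect_markers(mesh: SurfaceMesh, contrast_threshold: float = 0.5) -> MarkerSet:
    """Detect painted dot markers by color contrast against the one-ring.

    A vertex's contrast is the Euclidean RGB distance between its color and the
    mean color of its one-ring neighbours.  Vertices above ``contrast_threshold``
    are grouped into connected components over mesh edges; each component yields
    one marker at the member vertex closest to the component's mean position.
    The measure is difference-based, hence invariant to global color offsets.
    """
    if mesh.colors is None:
        raise ValueError("marker detection requires per-vertex colors")
    rings = mesh.one_ring()
    contrast = np.zeros(mesh.n_vertices)
    for i, nb in enumerate(rings):
        if len(nb):
            contrast[i] = np.linalg.norm(mesh.colors[i] - mesh.colors[nb].mean(axis=0))
    candidate = contrast > contrast_threshold
    # connected components of the candidate set over mesh edges
    visited = np.zeros(mesh.n_vertices, bool)
    indices, positions = [], []
    for seed in np.flatnonzero(candidate):
        if visited[seed]:
            continue
        stack, comp = [seed], []
        visited[seed] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in rings[v]:
                if candidate[u] and not visited[u]:
                    visited[u] = True
                    stack.append(u)
        comp = np.array(comp)
        mean_pos = mesh.vertices[comp].mean(axis=0)
        best = comp[np.argmin(np.linalg.norm(mesh.vertices[comp] - mean_pos, axis=1))]
        indices.append(best)
        positions.append(mesh.vertices[best])
    if not indices:
        return MarkerSet(np.empty(0, np.int64), np.empty((0, 3)))
    order = np.argsort(indices)
    return MarkerSet(np.asarray(indices)[order], np.asarray(positions)[order])


def markers_at(mesh: SurfaceMesh, vertex_indices: np.ndarray) -> MarkerSet:
    """Marker set at known vertex indices (ground-truth/material markers)."""
    idx = np.asarray(vertex_indices, np.int64)
    return MarkerSet(idx, mesh.vertices[idx])
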