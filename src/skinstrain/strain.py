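"""Green-Lagrange surface strain from registered mesh sequences.

For each vertex a local deformation gradient F maps reference edge vectors to
their current counterparts; the neighbourhood is all vertices within a
distance threshold of the vertex.  A surface patch constrains only the two
in-plane directions, so the regression is augmented with the unit-normal pair
(n_ref -> n_cur), pinning the out-of-plane direction and making the recovery
exact whenever the neighbourhood transformation is affine.  The strain tensor
is E = (F^T F - I)/2 and its first invariant tr(E) - the sum of the principal
strains - is the scalar deformation measure visualised as a white-to-red heat
map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh, vertex_normals


@dataclass
class StrainField:
    """Per-vertex Green-Lagrange strain tensors and first invariants of one frame.

    Vertices whose neighbourhood fails the preconditions (too few neighbours,
    degenerate geometry) carry NaN entries and are listed in ``failed``.
    """

    tensors: np.ndarray  # (N, 3, 3), symmetric, dimensionless
    invariants: np.ndarray  # (N,), tr(E)
    failed: np.ndarray  # indices of vertices without a valid estimate

    @property
    def n_vertices(self) -> int:
        return len(self.invariants)

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.invariants)


def deformation_gradient(reference: np.ndarray, current: np.ndarray,
                         normals_ref: np.ndarray, normals_cur: np.ndarray,
                         vertex: int, radius_mm: float,
                         tree: cKDTree | None = None) -> np.ndarray:
    """Deformation gradient at one vertex by neighbourhood regression.

    Least-squares fit of F mapping reference edge vectors (x_j - x_i) to
    current edge vectors, augmented with the unit-normal pair scaled to the
    mean edge length so its weight matches the in-plane rows.

    Raises if fewer than 3 neighbours lie within ``radius_mm`` or the
    augmented neighbourhood is rank deficient.
    """
    tree = tree or cKDTree(reference)
    nb = tree.query_ball_point(reference[vertex], radius_mm)
    nb = [j for j in nb if j != vertex]
    if len(nb) < 3:
        raise ValueError(
            f"vertex {vertex}: only {len(nb)} neighbours within "
            f"{radius_mm:g} mm; increase the neighbourhood radius")
    d_ref = reference[nb] - reference[vertex]
    d_cur = current[nb] - current[vertex]
    scale = np.linalg.norm(d_ref, axis=1).mean()
    A = np.vstack([d_ref, scale * normals_ref[vertex]])
    Bm = np.vstack([d_cur, scale * normals_cur[vertex]])
    G = A.T @ A
    if np.linalg.matrix_rank(G, tol=1e-9 * max(np.trace(G), 1e-300)) < 3:
        raise ValueError(f"vertex {vertex}: degenerate (collinear) neighbourhood")
    Ft = np.linalg.solve(G, A.T @ Bm)
    return Ft.T


def _regression_rows(d_ref: np.ndarray, d_cur: np.ndarray,
                     n_ref: np.ndarray, n_cur: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """In-plane edge rows plus the scaled unit-normal pair (surface variant).

    Used by :func:`strain_field`: edge vectors are projected onto the
    respective tangent planes first, because on a curved surface raw edge
    chords span all of 3-space and their out-of-plane components contaminate
    the direction the normal row is meant to pin - surface strain must
    measure in-plane stretch only.  (The standalone
    :func:`deformation_gradient` keeps the raw regression, which recovers a
    consistent affine neighbourhood map exactly.)
    """
    d_ref_p = d_ref - np.outer(d_ref @ n_ref, n_ref)
    d_cur_p = d_cur - np.outer(d_cur @ n_cur, n_cur)
    scale = np.linalg.norm(d_ref_p, axis=1).mean()
    A = np.vstack([d_ref_p, scale * n_ref])
    Bm = np.vstack([d_cur_p, scale * n_cur])
    return A, Bm


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain tensor E = (F^T F - I)/2 (symmetric by construction)."""
    F = np.asarray(F, float)
    return 0.5 * (F.T @ F - np.eye(3))


def strain_invariant(E: np.ndarray) -> float:
    """First invariant tr(E): the sum of the principal strains."""
    return float(np.trace(E))


def strain_field(reference: SurfaceMesh, current_positions: np.ndarray,
                 radius_mm: float | None = None) -> StrainField:
    """Per-vertex F -> E -> tr(E) over a registered frame.

    ``current_positions`` must share the reference's vertex order (template
    correspondence).  The default neighbourhood radius is 2.5x the mean edge
    length.  Vertices failing the preconditions are flagged NaN, not
    fabricated.
    """
    current_positions = np.asarray(current_positions, float)
    if current_positions.shape != reference.vertices.shape:
        raise ValueError("current positions must match the reference vertex count")
    if radius_mm is None:
        radius_mm = 2.5 * reference.mean_edge_length()
    n_ref = reference.normals
    n_cur = vertex_normals(reference.with_vertices(current_positions))
    tree = cKDTree(reference.vertices)
    N = reference.n_vertices
    tensors = np.full((N, 3, 3), np.nan)
    invariants = np.full(N, np.nan)
    failed = []
    neighbourhoods = tree.query_ball_point(reference.vertices, radius_mm)
    for i in range(N):
        nb = [j for j in neighbourhoods[i] if j != i]
        if len(nb) < 3 or np.linalg.norm(n_ref[i]) == 0:
            failed.append(i)
            continue
        A, Bm = _regression_rows(reference.vertices[nb] - reference.vertices[i],
                                 current_positions[nb] - current_positions[i],
                                 n_ref[i], n_cur[i])
        G = A.T @ A
        try:
            Ft = np.linalg.solve(G, A.T @ Bm)
        except np.linalg.LinAlgError:
            failed.append(i)
            continue
        E = green_lagrange(Ft.T)
        tensors[i] = E
        invariants[i] = np.trace(E)
    return StrainField(tensors, invariants, np.asarray(failed, np.int64))


def heatmap_colors(invariants: np.ndarray, vmax: float | None = None) -> np.ndarray:
    """Linear white-to-red color ramp over [0, vmax] of the strain invariant."""
    inv = np.nan_to_num(np.asarray(invariants, float), nan=0.0)
    if vmax is None:
        vmax = float(max(inv.max(), 1e-12))
    s = np.clip(inv / vmax, 0.0, 1.0)
    colors = np.ones((len(inv), 3))
    colors[:, 1] = 1.0 - s
    colors[:, 2] = 1.0 - s
    return colors


def export_heatmap(reference: SurfaceMesh, current_positions: np.ndarray,
                   field: StrainField, path, vmax: float | None = None) -> None:
    """Write the deformed surface as a vertex-colored PLY strain heat map."""
    mesh = SurfaceMesh(np.asarray(current_positions, float),
                       reference.triangles.copy(),
                       heatmap_colors(field.invariants, vmax))
    mesh.save(path)
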