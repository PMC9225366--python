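"""Temporally constrained non-rigid registration of a template to a scan sequence.

The template deforms under per-vertex affine transforms composed with one
global rigid transform per frame,

    X_i = [T_i ; t_i] [R_r ; t_r],

and the deformation is found by minimising

    E = w_C E_C + w_F E_F + w_S (E_ACAP + E_consist + E_smooth) + w_T E_T,

where E_C penalises the normal-projected closest-point residual (out-of-surface
fit), E_F the full 3D residual of matched dot markers (in-surface sliding),
the spatial terms keep the deformation as-conformal-as-possible, consistent
and smooth over one-rings, and E_T is the temporal constraint on per-vertex
velocities and accelerations.

Positions and velocities are expressed through Newmark-beta time integration
in terms of the *current accelerations* [T_ddot ; t_ddot], which become the
unknowns of each frame's solve.  With closest points and the ACAP
linearisation frozen, every energy term is quadratic in the accelerations, so
each ICP iteration is one sparse linear least-squares solve.  Registering a
sequence is therefore a filtering pass: each frame is initialised from, and
regularised toward, the integrated state of the previous frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.signal import butter, lfilter, lfilter_zi
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .mesh import MarkerSet, SurfaceMesh, markers_at, detect_markers


# --------------------------------------------------------------------------
# state and parameters
# --------------------------------------------------------------------------

@dataclass
class FrameState:
    """Per-vertex affine transforms, their time derivatives, and the global rigid pose."""

    T: np.ndarray  # (N, 3, 3) linear parts
    t: np.ndarray  # (N, 3) translations, mm
    T_dot: np.ndarray
    t_dot: np.ndarray
    T_ddot: np.ndarray
    t_ddot: np.ndarray
    R_r: np.ndarray  # (3, 3) global rotation
    t_r: np.ndarray  # (3,) global translation, mm
    dT: float  # frame timestep, s

    @classmethod
    def identity(cls, n_vertices: int, dT: float) -> "FrameState":
        """Resting state: identity transforms, zero derivatives (first frame)."""
        eye = np.broadcast_to(np.eye(3), (n_vertices, 3, 3)).copy()
        z33 = np.zeros((n_vertices, 3, 3))
        z3 = np.zeros((n_vertices, 3))
        return cls(eye, z3.copy(), z33.copy(), z3.copy(), z33.copy(), z3.copy(),
                   np.eye(3), np.zeros(3), dT)

    @property
    def n_vertices(self) -> int:
        return len(self.t)

    def aligned_template(self, vertices: np.ndarray) -> np.ndarray:
        """Template vertices under the global rigid transform: x_hat = R_r x + t_r."""
        return vertices @ self.R_r.T + self.t_r

    def deformed_positions(self, vertices: np.ndarray) -> np.ndarray:
        """World positions X_i x_i = T_i (R_r x_i + t_r) + t_i."""
        x_hat = self.aligned_template(vertices)
        return np.einsum("nij,nj->ni", self.T, x_hat) + self.t

    def world_velocities(self, vertices: np.ndarray) -> np.ndarray:
        """Vertex velocities from the kinematic state (rigid pose held fixed)."""
        x_hat = self.aligned_template(vertices)
        return np.einsum("nij,nj->ni", self.T_dot, x_hat) + self.t_dot

    def world_accelerations(self, vertices: np.ndarray) -> np.ndarray:
        x_hat = self.aligned_template(vertices)
        return np.einsum("nij,nj->ni", self.T_ddot, x_hat) + self.t_ddot


@dataclass
class RegistrationParams:
    """Weights and solver settings.

    ``w_T`` and ``w_v`` are expressed in position-increment units: internally
    they are scaled by (beta dT^2/2)^2 and (beta dT / 2 gamma)^2 so that
    ``w_T = 1`` weighs the temporal prior comparably to 1 mm^2 of
    closest-point residual regardless of the frame rate.
    """

    w_C: float = 1.0
    w_F: float = 10.0
    w_S: float = 0.1
    w_T: float = 3000.0
    w_v: float = 0.1
    w_lin: float = 10.0
    w_acap: float = 1.0
    w_consist: float = 1.0
    w_smooth: float = 1.0
    beta: float = 0.4
    gamma: float = 0.9
    max_iterations: int = 50
    tol: float = 1e-4
    marker_threshold_factor: float = 3.0
    rigid_max_iterations: int = 20
    rigid_temporal_weight: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_C", "w_F", "w_S", "w_T", "w_v", "w_lin",
                     "w_acap", "w_consist", "w_smooth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.beta <= 0.5 and 0 <= self.gamma <= 1):
            raise ValueError("require 0 <= beta <= 0.5 and 0 <= gamma <= 1")

    def effective_temporal_weights(self, dT: float) -> tuple[float, float]:
        """(accel weight, velocity weight) applied to the raw squared derivatives."""
        mu = self.beta * dT**2 / 2.0
        nu = self.gamma * dT
        lam_a = self.w_T * mu**2
        lam_v = self.w_T * self.w_v * (mu / nu) ** 2 if nu > 0 else 0.0
        return lam_a, lam_v


@dataclass
class EnergyBreakdown:
    """The energy decomposition of one solve; ``total`` is the weighted sum."""

    e_closest: float
    e_feature: float
    e_acap: float
    e_consist: float
    e_smooth: float
    e_temporal: float
    w_C: float
    w_F: float
    w_S: float
    w_T: float

    @property
    def e_spatial(self) -> float:
        return self.e_acap + self.e_consist + self.e_smooth

    @property
    def total(self) -> float:
        return (self.w_C * self.e_closest + self.w_F * self.e_feature
                + self.w_S * self.e_spatial + self.w_T * self.e_temporal)


# --------------------------------------------------------------------------
# correspondence
# --------------------------------------------------------------------------

def closest_points(points: np.ndarray, target: SurfaceMesh | np.ndarray) -> np.ndarray:
    """Index of the nearest target vertex for every query point (point-to-point)."""
    tv = target.vertices if isinstance(target, SurfaceMesh) else np.asarray(target)
    if len(tv) == 0:
        raise ValueError("target is empty")
    _, idx = cKDTree(tv).query(np.asarray(points, float))
    return idx


def match_markers(template_markers: MarkerSet, target_markers: MarkerSet,
                  prev_median_distance: float = np.inf,
                  factor: float = 3.0) -> tuple[np.ndarray, float]:
    """Mutual-nearest-neighbour marker pairing with a median-based distance gate.

    Pairs whose 3D distance exceeds ``factor * prev_median_distance`` are
    discarded (false-positive control).  Returns ``(pairs, median)`` where
    ``pairs[:, 0]`` indexes ``template_markers`` and ``pairs[:, 1]`` indexes
    ``target_markers``; ``median`` is the median distance of the kept pairs.
    An empty pairing keeps the previous median.
    """
    if len(template_markers) == 0 or len(target_markers) == 0:
        raise ValueError("both marker sets must be non-empty")
    p, q = template_markers.positions, target_markers.positions
    fwd = cKDTree(q).query(p)[1]          # template -> target
    bwd = cKDTree(p).query(q)[1]          # target -> template
    ti = np.arange(len(p))
    mutual = bwd[fwd] == ti
    dist = np.linalg.norm(p - q[fwd], axis=1)
    threshold = (factor * prev_median_distance
                 if np.isfinite(prev_median_distance) else np.inf)
    keep = mutual & (dist <= threshold)
    if not keep.any():
        warnings.warn("all marker pairs rejected by the distance gate; "
                      "feature term inactive this frame", stacklevel=2)
        return np.empty((0, 2), dtype=np.int64), float(prev_median_distance)
    pairs = np.stack([ti[keep], fwd[keep]], axis=1).astype(np.int64)
    return pairs, float(np.median(dist[keep]))


def rigid_prealign(template: SurfaceMesh, target: SurfaceMesh,
                   marker_pairs: tuple[np.ndarray, np.ndarray] | None = None,
                   prev_state: FrameState | None = None,
                   params: RegistrationParams | None = None,
                   temporal_weight: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Global rigid alignment by weighted rigid ICP over closest points and markers.

    ``marker_pairs`` is ``(template_vertex_indices, target_positions)``.  With
    ``temporal_weight`` > 0 the increment from the previous frame's pose is
    shrunk by 1/(1+w) (closed form of a quadratic penalty on the pose change).
    Raises if the correspondence covariance is rank deficient (collinear or
    fewer than 3 independent correspondences).
    """
    params = params or RegistrationParams()
    R = prev_state.R_r.copy() if prev_state is not None else np.eye(3)
    t = prev_state.t_r.copy() if prev_state is not None else np.zeros(3)
    x = template.vertices
    tree = cKDTree(target.vertices)
    mi, mq = (None, None)
    if marker_pairs is not None and len(marker_pairs[0]):
        mi = np.asarray(marker_pairs[0], np.int64)
        mq = np.asarray(marker_pairs[1], float)
    for _ in range(params.rigid_max_iterations):
        p = x @ R.T + t
        y = target.vertices[tree.query(p)[1]]
        src = [x]
        dst = [y]
        w = [np.full(len(x), params.w_C)]
        if mi is not None:
            src.append(x[mi])
            dst.append(mq)
            w.append(np.full(len(mi), params.w_F))
        src, dst = np.concatenate(src), np.concatenate(dst)
        w = np.concatenate(w)[:, None]
        sbar = (w * src).sum(0) / w.sum()
        dbar = (w * dst).sum(0) / w.sum()
        H = (w * (src - sbar)).T @ (dst - dbar)
        U, S, Vt = np.linalg.svd(H)
        if S[1] <= 1e-12 * max(S[0], 1e-300):
            raise ValueError("degenerate correspondences: covariance rank < 2 "
                             "(collinear or coincident points)")
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        R_new = Vt.T @ D @ U.T
        t_new = dbar - R_new @ sbar
        if (np.abs(R_new - R).max() < 1e-12 and np.abs(t_new - t).max() < 1e-12):
            R, t = R_new, t_new
            break
        R, t = R_new, t_new
    if temporal_weight > 0 and prev_state is not None:
        shrink = 1.0 / (1.0 + temporal_weight)
        drot = Rotation.from_matrix(prev_state.R_r.T @ R).as_rotvec()
        R = prev_state.R_r @ Rotation.from_rotvec(shrink * drot).as_matrix()
        t = prev_state.t_r + shrink * (t - prev_state.t_r)
    return R, t


# --------------------------------------------------------------------------
# energies
# --------------------------------------------------------------------------

def projected_closest_targets(x_hat: np.ndarray, normals: np.ndarray,
                              prev_R_r: np.ndarray, target_positions: np.ndarray,
                              correspondence: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal-projected closest-point targets y_tilde and the valid-normal mask.

    y_tilde_i = x_hat_i + ((R_prev n_i) . (y_i - x_hat_i)) R_prev n_i keeps only
    the out-of-surface component of the closest-point displacement; vertices
    with zero normals are flagged invalid and skipped by the energy.
    """
    m = normals @ prev_R_r.T
    valid = np.linalg.norm(m, axis=1) > 0.5
    y = target_positions[correspondence]
    coef = np.einsum("ni,ni->n", m, y - x_hat)
    return x_hat + coef[:, None] * m, valid


def energy_closest(state: FrameState, template: SurfaceMesh, target: SurfaceMesh,
                   correspondence: np.ndarray,
                   prev_R_r: np.ndarray | None = None) -> float:
    """E_C = sum_i || X_i x_i - y_tilde_i ||^2 over vertices with valid normals."""
    prev_R_r = state.R_r if prev_R_r is None else prev_R_r
    x_hat = state.aligned_template(template.vertices)
    y_tilde, valid = projected_closest_targets(
        x_hat, template.normals, prev_R_r, target.vertices, correspondence)
    r = state.deformed_positions(template.vertices) - y_tilde
    return float((r[valid] ** 2).sum())


def energy_feature(state: FrameState, template: SurfaceMesh,
                   marker_indices: np.ndarray, marker_targets: np.ndarray) -> float:
    """E_F = sum_j || X_j p_j - q_j ||^2 (full 3D marker residual)."""
    if len(marker_indices) == 0:
        return 0.0
    p = state.deformed_positions(template.vertices)[np.asarray(marker_indices, np.int64)]
    return float(((p - np.asarray(marker_targets, float)) ** 2).sum())


def closest_scaled_rotation(T: np.ndarray) -> np.ndarray:
    """Per-vertex closest scaled rotation s_i R_i to T_i in Frobenius norm (SVD)."""
    U, S, Vt = np.linalg.svd(T)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.zeros_like(T)
    D[:, 0, 0] = D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = U @ D @ Vt
    s = (S[:, 0] + S[:, 1] + d * S[:, 2]) / 3.0
    return s[:, None, None] * R


def energy_spatial(state: FrameState, template: SurfaceMesh,
                   sub_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                   acap_targets: np.ndarray | None = None
                   ) -> tuple[float, float, float]:
    """(E_ACAP, E_consist, E_smooth) of the current per-vertex transforms.

    E_ACAP measures the distance of each T_i to its closest scaled rotation
    (conformality); E_consist the disagreement of neighbouring affine maps when
    both are evaluated at the neighbour's position; E_smooth the one-ring
    variation of (T, t).  ``acap_targets`` freezes the scaled rotations at a
    linearisation point (used by the solver); by default they are the exact
    per-vertex projections.
    """
    T, t = state.T, state.t
    P = closest_scaled_rotation(T) if acap_targets is None else acap_targets
    e_acap = float(((T - P) ** 2).sum())
    x_hat = state.aligned_template(template.vertices)
    pi, pj = _directed_pairs(template)
    map_i = np.einsum("pij,pj->pi", T[pi], x_hat[pj]) + t[pi]
    map_j = np.einsum("pij,pj->pi", T[pj], x_hat[pj]) + t[pj]
    e_consist = float(((map_i - map_j) ** 2).sum())
    e_smooth = float(((T[pi] - T[pj]) ** 2).sum() + ((t[pi] - t[pj]) ** 2).sum())
    wa, wc, ws = sub_weights
    return wa * e_acap, wc * e_consist, ws * e_smooth


def energy_temporal(T_ddot: np.ndarray, t_ddot: np.ndarray,
                    T_dot: np.ndarray, t_dot: np.ndarray,
                    w_v: float, w_lin: float) -> float:
    """E_T = sum_i (||t_ddot||^2 + w_lin tr(T_ddot^T T_ddot))
            + w_v sum_i (||t_dot||^2 + w_lin tr(T_dot^T T_dot))."""
    acc = (t_ddot ** 2).sum() + w_lin * (T_ddot ** 2).sum()
    vel = (t_dot ** 2).sum() + w_lin * (T_dot ** 2).sum()
    return float(acc + w_v * vel)


def newmark_update(prev: FrameState, T_ddot: np.ndarray, t_ddot: np.ndarray,
                   beta: float, gamma: float, dT: float
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Newmark-beta integration of the current accelerations.

    [T t]_k    = [T t]_{k-1} + dT [Td td]_{k-1}
                 + dT^2/2 ((1-beta) [Tdd tdd]_{k-1} + beta [Tdd tdd]_k)
    [Td td]_k  = [Td td]_{k-1} + dT ((1-gamma) [Tdd tdd]_{k-1} + gamma [Tdd tdd]_k)

    Linear in the current acceleration; exact for constant-acceleration motion
    for any (beta, gamma).
    """
    if dT <= 0:
        raise ValueError("dT must be positive")
    cT, ct, cTd, ctd = newmark_base(prev, beta, gamma, dT)
    mu = beta * dT**2 / 2.0
    nu = gamma * dT
    return cT + mu * T_ddot, ct + mu * t_ddot, cTd + nu * T_ddot, ctd + nu * t_ddot


def newmark_base(prev: FrameState, beta: float, gamma: float, dT: float
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The acceleration-free (inertial predictor) part of the Newmark update."""
    half = dT**2 / 2.0
    cT = prev.T + dT * prev.T_dot + half * (1 - beta) * prev.T_ddot
    ct = prev.t + dT * prev.t_dot + half * (1 - beta) * prev.t_ddot
    cTd = prev.T_dot + dT * (1 - gamma) * prev.T_ddot
    ctd = prev.t_dot + dT * (1 - gamma) * prev.t_ddot
    return cT, ct, cTd, ctd


# --------------------------------------------------------------------------
# the per-frame quadratic solve
# --------------------------------------------------------------------------

def linear_weight_scale(x_hat: np.ndarray) -> float:
    """Length^2 scale putting linear-transform derivatives in position units.

    An entry of T_ddot moves a vertex through a lever arm of order its
    distance from the mesh centroid, so the temporal penalty on T-derivatives
    is scaled by the mean squared centroid distance; with ``w_lin = 1`` the
    damping of T-driven motion then matches that of translations at the RMS
    radius.  Without this the linear channel is orders of magnitude
    underdamped and the sequential filtering loop is unstable.
    """
    centered = x_hat - x_hat.mean(axis=0)
    return float((centered**2).sum(axis=1).mean())


def _directed_pairs(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    rings = mesh.one_ring()
    pi = np.concatenate([np.full(len(nb), i, np.int64) for i, nb in enumerate(rings)])
    pj = np.concatenate(rings) if rings else np.empty(0, np.int64)
    return pi, pj


class _RowBuilder:
    """Accumulates weighted rows of the sparse least-squares system."""

    def __init__(self) -> None:
        self.rows: list[np.ndarray] = []
        self.cols: list[np.ndarray] = []
        self.vals: list[np.ndarray] = []
        self.rhs: list[np.ndarray] = []
        self.n_rows = 0

    def add(self, cols: np.ndarray, vals: np.ndarray, rhs: np.ndarray,
            sqrt_w: float) -> None:
        """cols/vals: (n_rows, nnz_per_row); rhs: (n_rows,)."""
        if sqrt_w == 0.0 or len(rhs) == 0:
            return
        n, m = cols.shape
        self.rows.append(np.repeat(np.arange(self.n_rows, self.n_rows + n), m))
        self.cols.append(cols.ravel())
        self.vals.append(sqrt_w * vals.ravel())
        self.rhs.append(sqrt_w * np.asarray(rhs, float))
        self.n_rows += n

    def build(self, n_cols: int) -> tuple[sp.csr_matrix, np.ndarray]:
        J = sp.csr_matrix(
            (np.concatenate(self.vals),
             (np.concatenate(self.rows), np.concatenate(self.cols))),
            shape=(self.n_rows, n_cols))
        return J, np.concatenate(self.rhs)


def _col_T(i: np.ndarray, r: int) -> np.ndarray:
    """Columns of row r of T_ddot for vertices i: entries (r,0),(r,1),(r,2)."""
    base = 12 * i[:, None] + 3 * r
    return base + np.arange(3)


def _col_t(i: np.ndarray, r: int) -> np.ndarray:
    return 12 * i + 9 + r


def assemble_system(template: SurfaceMesh, x_hat: np.ndarray,
                    y_tilde: np.ndarray, valid: np.ndarray,
                    marker_indices: np.ndarray, marker_targets: np.ndarray,
                    acap_targets: np.ndarray,
                    base: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
                    params: RegistrationParams, dT: float
                    ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the sparse least-squares system J a = b in the stacked
    accelerations a (12 per vertex: T_ddot row-major then t_ddot)."""
    N = len(x_hat)
    cT, ct, cTd, ctd = base
    mu = params.beta * dT**2 / 2.0
    nu = params.gamma * dT
    lam_a, lam_v = params.effective_temporal_weights(dT)
    B = _RowBuilder()

    # E_C: residual rows  mu (Tdd_i x_hat_i + tdd_i) - (y_tilde - Tc x_hat - tc)
    iv = np.flatnonzero(valid)
    base_pos = np.einsum("nij,nj->ni", cT, x_hat) + ct
    for r in range(3):
        cols = np.concatenate([_col_T(iv, r), _col_t(iv, r)[:, None]], axis=1)
        vals = np.concatenate(
            [mu * x_hat[iv], np.full((len(iv), 1), mu)], axis=1)
        B.add(cols, vals, (y_tilde - base_pos)[iv, r], np.sqrt(params.w_C))

    # E_F: full 3D marker rows
    mi = np.asarray(marker_indices, np.int64)
    if len(mi):
        q = np.asarray(marker_targets, float)
        for r in range(3):
            cols = np.concatenate([_col_T(mi, r), _col_t(mi, r)[:, None]], axis=1)
            vals = np.concatenate(
                [mu * x_hat[mi], np.full((len(mi), 1), mu)], axis=1)
            B.add(cols, vals, q[:, r] - base_pos[mi, r], np.sqrt(params.w_F))

    # E_ACAP: T rows toward the frozen scaled rotations
    alli = np.arange(N)
    for r in range(3):
        for c in range(3):
            cols = (12 * alli + 3 * r + c)[:, None]
            vals = np.full((N, 1), mu)
            B.add(cols, vals, acap_targets[:, r, c] - cT[:, r, c],
                  np.sqrt(params.w_S * params.w_acap))

    # E_consist and E_smooth over directed one-ring pairs
    pi, pj = _directed_pairs(template)
    if len(pi):
        w_cons = np.sqrt(params.w_S * params.w_consist)
        base_ij = (np.einsum("pij,pj->pi", cT[pi], x_hat[pj]) + ct[pi]
                   - np.einsum("pij,pj->pi", cT[pj], x_hat[pj]) - ct[pj])
        for r in range(3):
            cols = np.concatenate(
                [_col_T(pi, r), _col_t(pi, r)[:, None],
                 _col_T(pj, r), _col_t(pj, r)[:, None]], axis=1)
            vals = np.concatenate(
                [mu * x_hat[pj], np.full((len(pi), 1), mu),
                 -mu * x_hat[pj], np.full((len(pi), 1), -mu)], axis=1)
            B.add(cols, vals, -base_ij[:, r], w_cons)

        w_sm = np.sqrt(params.w_S * params.w_smooth)
        for r in range(3):
            for c in range(3):
                cols = np.stack([12 * pi + 3 * r + c, 12 * pj + 3 * r + c], axis=1)
                vals = np.tile([mu, -mu], (len(pi), 1))
                B.add(cols, vals, -(cT[pi, r, c] - cT[pj, r, c]), w_sm)
        for r in range(3):
            cols = np.stack([_col_t(pi, r), _col_t(pj, r)], axis=1)
            vals = np.tile([mu, -mu], (len(pi), 1))
            B.add(cols, vals, -(ct[pi, r] - ct[pj, r]), w_sm)

    # E_T: acceleration rows (unknowns directly) and velocity rows (via Newmark)
    w_lin_eff = params.w_lin * linear_weight_scale(x_hat)
    if lam_a > 0:
        for r in range(3):
            B.add(_col_t(alli, r)[:, None], np.ones((N, 1)),
                  np.zeros(N), np.sqrt(lam_a))
            for c in range(3):
                B.add((12 * alli + 3 * r + c)[:, None], np.ones((N, 1)),
                      np.zeros(N), np.sqrt(lam_a * w_lin_eff))
    if lam_v > 0 and nu > 0:
        for r in range(3):
            B.add(_col_t(alli, r)[:, None], np.full((N, 1), nu),
                  -ctd[:, r], np.sqrt(lam_v))
            for c in range(3):
                B.add((12 * alli + 3 * r + c)[:, None], np.full((N, 1), nu),
                      -cTd[:, r, c], np.sqrt(lam_v * w_lin_eff))

    return B.build(12 * N)


def solve_accelerations(J: sp.csr_matrix, b: np.ndarray,
                        ridge: float = 1e-12) -> np.ndarray:
    """Normal-equation solve of min ||J a - b||^2 with a tiny relative ridge."""
    JtJ = (J.T @ J).tocsc()
    diag_mean = JtJ.diagonal().mean()
    if not np.isfinite(diag_mean) or diag_mean <= 0:
        raise ValueError("non-finite or empty least-squares system")
    A = JtJ + ridge * diag_mean * sp.identity(JtJ.shape[0], format="csc")
    a = spla.spsolve(A, J.T @ b)
    if not np.all(np.isfinite(a)):
        raise ValueError("solver produced non-finite accelerations")
    return a


# --------------------------------------------------------------------------
# per-frame and per-sequence registration
# --------------------------------------------------------------------------

def _frame_energy(state: FrameState, template: SurfaceMesh, target: SurfaceMesh,
                  correspondence: np.ndarray, prev_R_r: np.ndarray,
                  marker_indices: np.ndarray, marker_targets: np.ndarray,
                  params: RegistrationParams, acap_targets=None) -> EnergyBreakdown:
    e_c = energy_closest(state, template, target, correspondence, prev_R_r)
    e_f = energy_feature(state, template, marker_indices, marker_targets)
    e_a, e_co, e_sm = energy_spatial(
        state, template, (params.w_acap, params.w_consist, params.w_smooth),
        acap_targets=acap_targets)
    lam_a, lam_v = params.effective_temporal_weights(state.dT)
    w_v_eff = lam_v / lam_a if lam_a > 0 else 0.0
    w_lin_eff = params.w_lin * linear_weight_scale(
        state.aligned_template(template.vertices))
    e_t = energy_temporal(state.T_ddot, state.t_ddot, state.T_dot, state.t_dot,
                          w_v_eff, w_lin_eff)
    return EnergyBreakdown(e_c, e_f, e_a, e_co, e_sm, e_t,
                           params.w_C, params.w_F, params.w_S, lam_a)


def register_frame(template: SurfaceMesh, target: SurfaceMesh,
                   prev_state: FrameState, params: RegistrationParams,
                   marker_indices: np.ndarray | None = None,
                   marker_targets: np.ndarray | None = None,
                   rigid: tuple[np.ndarray, np.ndarray] | None = None
                   ) -> tuple[FrameState, EnergyBreakdown, np.ndarray, dict]:
    """Register one target frame: ICP loop of closest-point update, sparse
    quadratic solve for the accelerations, and Newmark integration.

    Returns ``(state, energies, deformed_positions, info)`` where ``info``
    carries the iteration count and the per-iteration total-energy history
    (non-increasing by construction: a step that would increase the energy is
    reverted and the loop stops).
    """
    N = template.n_vertices
    dT = prev_state.dT
    if marker_indices is None:
        marker_indices = np.empty(0, np.int64)
        marker_targets = np.empty((0, 3))
    R_r, t_r = rigid if rigid is not None else (prev_state.R_r, prev_state.t_r)
    prev_R_r = prev_state.R_r

    x_hat = template.vertices @ R_r.T + t_r
    normals = template.normals
    tree = cKDTree(target.vertices)
    if params.w_T > 0:
        base = newmark_base(prev_state, params.beta, params.gamma, dT)
    else:
        # Without the temporal constraint the frames are registered
        # independently: the previous transforms only initialise the solve,
        # and no kinematic state is extrapolated (nothing would damp it).
        static_prev = replace(prev_state,
                              T_dot=np.zeros_like(prev_state.T_dot),
                              t_dot=np.zeros_like(prev_state.t_dot),
                              T_ddot=np.zeros_like(prev_state.T_ddot),
                              t_ddot=np.zeros_like(prev_state.t_ddot))
        base = newmark_base(static_prev, params.beta, params.gamma, dT)
        prev_state = static_prev

    def make_state(T, t, Td, td, Tdd, tdd) -> FrameState:
        return FrameState(T, t, Td, td, Tdd, tdd, R_r, t_r, dT)

    # iterate from the inertial prediction (zero current acceleration)
    zero33, zero3 = np.zeros((N, 3, 3)), np.zeros((N, 3))
    state = make_state(base[0].copy(), base[1].copy(), base[2].copy(),
                       base[3].copy(), zero33, zero3)
    pos = state.deformed_positions(template.vertices)
    corr = tree.query(pos)[1]
    energies = _frame_energy(state, template, target, corr, prev_R_r,
                             marker_indices, marker_targets, params)
    history = [energies.total]

    for it in range(params.max_iterations):
        y_tilde, valid = projected_closest_targets(
            x_hat, normals, prev_R_r, target.vertices, corr)
        acap_targets = closest_scaled_rotation(state.T)
        J, b = assemble_system(template, x_hat, y_tilde, valid,
                               marker_indices, marker_targets, acap_targets,
                               base, params, dT)
        a = solve_accelerations(J, b)
        Tdd = a.reshape(N, 12)[:, :9].reshape(N, 3, 3)
        tdd = a.reshape(N, 12)[:, 9:]
        T, t, Td, td = newmark_update(prev_state, Tdd, tdd,
                                      params.beta, params.gamma, dT)
        new_state = make_state(T, t, Td, td, Tdd, tdd)
        new_pos = new_state.deformed_positions(template.vertices)
        new_corr = tree.query(new_pos)[1]
        new_energies = _frame_energy(new_state, template, target, new_corr,
                                     prev_R_r, marker_indices, marker_targets,
                                     params)
        if not np.isfinite(new_energies.total):
            raise ValueError(f"non-finite energy at ICP iteration {it}")
        if new_energies.total > history[-1]:
            break  # keep the previous (lower-energy) iterate
        state, pos, corr, energies = new_state, new_pos, new_corr, new_energies
        history.append(energies.total)
        denom = max(history[-2], 1e-30)
        if (history[-2] - history[-1]) / denom < params.tol:
            break

    info = {"iterations": len(history) - 1, "energy_history": history}
    return state, energies, pos, info


@dataclass
class RegistrationResults:
    """Trajectory estimates and diagnostics of a sequence registration."""

    positions: np.ndarray  # (K, N, 3) mm
    velocities: np.ndarray  # (K, N, 3) mm/s, from the kinematic state
    accelerations: np.ndarray  # (K, N, 3) mm/s^2
    energies: list  # final EnergyBreakdown per frame
    energy_histories: list  # per-frame per-iteration totals
    states: list  # final FrameState per frame
    params: RegistrationParams
    template: SurfaceMesh = field(repr=False)
    frame_rate_hz: float = 100.0

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def iterations(self) -> np.ndarray:
        return np.array([len(h) - 1 for h in self.energy_histories])

    def finite_difference_kinematics(self) -> tuple[np.ndarray, np.ndarray]:
        """(velocities, accelerations) by central differences of the positions."""
        return finite_difference_kinematics(self.positions, 1.0 / self.frame_rate_hz)

    def strain_fields(self, radius_mm: float | None = None) -> list:
        """Per-frame Green-Lagrange strain fields of the registered surfaces."""
        from .strain import strain_field
        return [strain_field(self.template, self.positions[k], radius_mm)
                for k in range(self.n_frames)]

    def summary(self) -> str:
        e = self.energies[-1]
        lines = [
            "Temporally constrained non-rigid registration",
            "=" * 45,
            f"frames registered        {self.n_frames}",
            f"template vertices        {self.template.n_vertices}",
            f"mean ICP iterations      {self.iterations.mean():.1f}",
            f"weights (C,F,S,T)        ({self.params.w_C}, {self.params.w_F}, "
            f"{self.params.w_S}, {self.params.w_T})",
            f"Newmark (beta, gamma)    ({self.params.beta}, {self.params.gamma})",
            f"final-frame energy       {e.total:.4g}",
            f"  closest-point  E_C     {e.e_closest:.4g}",
            f"  marker feature E_F     {e.e_feature:.4g}",
            f"  spatial        E_S     {e.e_spatial:.4g}",
            f"  temporal       E_T     {e.e_temporal:.4g}",
        ]
        return "\n".join(lines)


class TemporalRegistration:
    """Model object: register a template onto a time-ordered target sequence.

    Parameters
    ----------
    template : SurfaceMesh
        The (noise-free) template; its vertex order defines correspondence.
    targets : sequence of SurfaceMesh
        Time-ordered target scans at a constant frame rate.
    frame_rate_hz : float
        Acquisition rate of the targets.
    params : RegistrationParams, optional
        Energy weights and solver settings.
    template_marker_indices : array, optional
        Known marker vertices on the template; if omitted and the template has
        colors, markers are detected by color contrast.
    """

    def __init__(self, template: SurfaceMesh, targets, frame_rate_hz: float,
                 params: RegistrationParams | None = None,
                 template_marker_indices=None, contrast_threshold: float = 0.5):
        if len(targets) < 1:
            raise ValueError("need at least one target frame")
        self.template = template
        self.targets = list(targets)
        self.frame_rate_hz = float(frame_rate_hz)
        self.params = params or RegistrationParams()
        self.contrast_threshold = contrast_threshold
        if template_marker_indices is not None:
            self.template_markers = markers_at(template, template_marker_indices)
        elif template.colors is not None:
            self.template_markers = detect_markers(template, contrast_threshold)
        else:
            self.template_markers = MarkerSet(np.empty(0, np.int64),
                                              np.empty((0, 3)))

    def fit(self, verbose: bool = False) -> RegistrationResults:
        """Sequential filtering pass over all frames; carries the kinematic state."""
        params = self.params
        dT = 1.0 / self.frame_rate_hz
        N = self.template.n_vertices
        state = FrameState.identity(N, dT)
        prev_median = np.inf
        marker_floor = 0.5 * self.template.mean_edge_length()
        K = len(self.targets)
        pos = np.empty((K, N, 3))
        vel = np.empty_like(pos)
        acc = np.empty_like(pos)
        energies, histories, states = [], [], []
        for k, target in enumerate(self.targets):
            try:
                mi, mq = self._match_frame_markers(state, target, prev_median)
                if len(mi):
                    pairs_for_rigid = (mi, mq)
                else:
                    pairs_for_rigid = None
                rigid_w = (params.rigid_temporal_weight
                           if params.w_T > 0 else 0.0)
                R_r, t_r = rigid_prealign(self.template, target,
                                          pairs_for_rigid, state, params,
                                          temporal_weight=rigid_w)
                state, e, p, info = register_frame(
                    self.template, target, state, params,
                    marker_indices=mi, marker_targets=mq, rigid=(R_r, t_r))
                if len(mi):
                    cur = state.deformed_positions(self.template.vertices)[mi]
                    d = np.linalg.norm(cur - mq, axis=1)
                    prev_median = max(float(np.median(d)), marker_floor)
            except Exception as exc:
                raise RuntimeError(f"registration failed at frame {k}: {exc}") from exc
            pos[k] = p
            vel[k] = state.world_velocities(self.template.vertices)
            acc[k] = state.world_accelerations(self.template.vertices)
            energies.append(e)
            histories.append(info["energy_history"])
            states.append(state)
            if verbose:
                print(f"frame {k:4d}: {info['iterations']:2d} iterations, "
                      f"E = {e.total:.5g}")
        return RegistrationResults(pos, vel, acc, energies, histories, states,
                                   params, self.template, self.frame_rate_hz)

    def _match_frame_markers(self, state: FrameState, target: SurfaceMesh,
                             prev_median: float) -> tuple[np.ndarray, np.ndarray]:
        """Detect target markers and pair them with the template's, gated by
        the previous frame's median matching distance."""
        tm = self.template_markers
        if len(tm) == 0 or target.colors is None:
            return np.empty(0, np.int64), np.empty((0, 3))
        tgt = detect_markers(target, self.contrast_threshold)
        if len(tgt) == 0:
            return np.empty(0, np.int64), np.empty((0, 3))
        cur = MarkerSet(tm.vertex_indices,
                        state.deformed_positions(self.template.vertices)[
                            tm.vertex_indices])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs, _ = match_markers(cur, tgt, prev_median,
                                     self.params.marker_threshold_factor)
        if len(pairs) == 0:
            return np.empty(0, np.int64), np.empty((0, 3))
        return tm.vertex_indices[pairs[:, 0]], tgt.positions[pairs[:, 1]]


def register_sequence(template: SurfaceMesh, targets, frame_rate_hz: float,
                      params: RegistrationParams | None = None,
                      **kwargs) -> RegistrationResults:
    """Functional wrapper around :class:`TemporalRegistration`."""
    return TemporalRegistration(template, targets, frame_rate_hz, params,
                                **kwargs).fit()


# --------------------------------------------------------------------------
# baselines
# --------------------------------------------------------------------------

def butterworth_baseline(positions: np.ndarray, order: int = 7,
                         cutoff_hz: float = 10.0,
                         rate_hz: float = 100.0) -> np.ndarray:
    """Low-pass Butterworth filtering of a trajectory along the frame axis.

    The comparison baseline for registration without the temporal constraint:
    a causal filter initialised at the first frame's steady state (unit DC
    gain, so constant signals pass unchanged).
    """
    if rate_hz <= 2 * cutoff_hz:
        raise ValueError("cutoff frequency must be below the Nyquist rate")
    positions = np.asarray(positions, float)
    flat = positions.reshape(positions.shape[0], -1)
    b, a = butter(order, cutoff_hz, fs=rate_hz, btype="low")
    zi = lfilter_zi(b, a)
    out = np.empty_like(flat)
    for j in range(flat.shape[1]):
        out[:, j], _ = lfilter(b, a, flat[:, j], zi=zi * flat[0, j])
    return out.reshape(positions.shape)


def finite_difference_kinematics(positions: np.ndarray, dt: float
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """(velocity, acceleration) by second-order finite differences in time."""
    vel = np.gradient(positions, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    return vel, acc
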