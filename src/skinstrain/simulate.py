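"""Synthetic deforming-surface sequences with analytic ground truth.

The generator emulates the study conditions used to validate the registration:
a tubular "muscle" surface of length 120 mm whose radius bulges radially in
proportion to a per-muscle activity profile, sampled at 100 Hz for one second,
with painted dot markers and i.i.d. per-vertex Gaussian noise added to every
target frame.  Because the displacement field is analytic, the sequence
carries closed-form ground-truth positions, velocities, accelerations and
surface strain, which the evaluation harness compares against.

Geometry.  The template is a structured tube (rings x axial stations) of
radius ``radius_mm``.  Each simulated muscle m contributes a radial bulge

    u_r(z, t) = bulge_amplitude_mm * a_m(t) * w_m(z),

where w_m is a C^1 cosine-squared axial window (peak 1) centred at a distinct
axial station.  Two muscles at 0.35 L and 0.65 L emulate the gastrocnemius /
soleus arrangement on the calf.

Ground-truth surface strain.  With r(z,t) the deformed radius, the in-plane
principal stretches of the tube surface relative to frame 0 are
circumferential lam_th = r(z,t)/r(z,0) and axial
lam_z = sqrt((1+dr/dz(t)^2)/(1+dr/dz(0)^2)); the first invariant of the
Green-Lagrange tensor (out-of-plane stretch 1) is
I = (lam_th^2 + lam_z^2 - 2)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .emg import ActivitySeries
from .mesh import SurfaceMesh

_BASE_COLOR = 0.85
_DOT_COLOR = 0.15


@dataclass
class SimConfig:
    """Configuration of the deforming-tube simulator (defaults are the study conditions)."""

    length_mm: float = 120.0
    n_frames: int = 100
    frame_rate_hz: float = 100.0
    radius_mm: float = 20.0
    bulge_amplitude_mm: float = 5.0
    activity_profile: np.ndarray | None = None  # (n_frames, n_muscles) in [0, 1]
    noise_sigma_mm: float = 0.5
    n_markers: int = 30
    seed: int = 0
    n_circumferential: int = 24
    n_axial: int = 40
    muscle_centers_frac: tuple = (0.35, 0.65)  # axial bulge stations, fraction of length
    window_halfwidth_frac: float = 0.18

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sigma_mm < 0:
            raise ValueError("noise_sigma_mm must be >= 0")
        if self.activity_profile is None:
            self.activity_profile = default_activity_profile(
                self.n_frames, self.frame_rate_hz, len(self.muscle_centers_frac))
        self.activity_profile = np.atleast_2d(
            np.asarray(self.activity_profile, dtype=np.float64))
        if self.activity_profile.shape[0] == 1 and self.n_frames > 1:
            self.activity_profile = self.activity_profile.T
        if self.activity_profile.shape[0] != self.n_frames:
            raise ValueError("activity_profile length must equal n_frames")

    @property
    def n_muscles(self) -> int:
        return self.activity_profile.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        """Target-frame times t_k = k / rate, k = 1..n_frames (template at t = 0)."""
        return np.arange(1, self.n_frames + 1) / self.frame_rate_hz


def default_activity_profile(n_frames: int, rate_hz: float, n_muscles: int = 2) -> np.ndarray:
    """Gradual-expansion activation in [0, 1]: each muscle rises smoothly and
    monotonically from rest to full activation over the sequence (the surface
    gradually expands with activity), with distinct waveforms per muscle."""
    t = np.arange(1, n_frames + 1) / rate_hz
    span = n_frames / rate_hz
    base = np.sin(0.5 * np.pi * t / span) ** 2
    cols = [base ** (m + 1) for m in range(n_muscles)]
    return np.stack(cols, axis=1)


@dataclass
class SimSequence:
    """A simulated sequence: noisy targets plus analytic ground truth."""

    template: SurfaceMesh
    targets: list  # list[SurfaceMesh], length n_frames
    truth_positions: np.ndarray  # (K, N, 3) mm
    truth_velocities: np.ndarray  # (K, N, 3) mm/s
    truth_accelerations: np.ndarray  # (K, N, 3) mm/s^2
    truth_strain_invariant: np.ndarray  # (K, N)
    activity: ActivitySeries
    marker_indices: np.ndarray
    seed: int
    config: SimConfig = field(repr=False)

    @property
    def n_frames(self) -> int:
        return len(self.targets)

    @property
    def dt(self) -> float:
        return 1.0 / self.config.frame_rate_hz


def _tube_topology(n_circ: int, n_axial: int) -> np.ndarray:
    """Open-ended structured tube triangulation with outward winding."""
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + j
            d = (i + 1) * n_circ + (j + 1) % n_circ
            faces.append((a, b, d))
            faces.append((a, d, c))
    return np.asarray(faces, dtype=np.int64)


def _marker_vertex_indices(cfg: SimConfig) -> np.ndarray:
    """Quasi-uniform marker vertices over the (station, ring) lattice."""
    idx = []
    for m in range(cfg.n_markers):
        station = int(np.floor((m + 0.5) * cfg.n_axial / cfg.n_markers))
        ring = int(np.floor((m * 0.6180339887498949) % 1.0 * cfg.n_circumferential))
        idx.append(station * cfg.n_circumferential + ring)
    return np.unique(np.asarray(idx, dtype=np.int64))


class _BulgeField:
    """Analytic radial displacement field of the tube and its derivatives."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        n_c, n_a = cfg.n_circumferential, cfg.n_axial
        theta = 2 * np.pi * np.arange(n_c) / n_c
        z = np.linspace(0.0, cfg.length_mm, n_a)
        self.z_grid, self.theta_grid = np.meshgrid(z, theta, indexing="ij")
        self.z = self.z_grid.ravel()
        self.e_r = np.stack(
            [np.cos(self.theta_grid.ravel()), np.sin(self.theta_grid.ravel()),
             np.zeros(n_c * n_a)], axis=1)
        # per-muscle axial windows and their z-derivative at the vertices
        self.w = np.stack([self._window(self.z, c) for c in cfg.muscle_centers_frac])
        self.dw = np.stack([self._window_dz(self.z, c) for c in cfg.muscle_centers_frac])
        # activity spline over [0, T] including the template's resting state
        t = np.concatenate([[0.0], cfg.frame_times])
        a = np.vstack([np.zeros((1, cfg.n_muscles)), cfg.activity_profile])
        self.spline = CubicSpline(t, a, axis=0)

    def _window(self, z: np.ndarray, center_frac: float) -> np.ndarray:
        cfg = self.cfg
        h = cfg.window_halfwidth_frac * cfg.length_mm
        d = z - center_frac * cfg.length_mm
        w = np.where(np.abs(d) < h, np.cos(np.pi * d / (2 * h)) ** 2, 0.0)
        return w

    def _window_dz(self, z: np.ndarray, center_frac: float) -> np.ndarray:
        cfg = self.cfg
        h = cfg.window_halfwidth_frac * cfg.length_mm
        d = z - center_frac * cfg.length_mm
        return np.where(np.abs(d) < h,
                        -np.pi / (2 * h) * np.sin(np.pi * d / h), 0.0)

    def radius(self, a: np.ndarray) -> np.ndarray:
        """Deformed radius per vertex for activity vector a (one entry per muscle)."""
        return self.cfg.radius_mm + self.cfg.bulge_amplitude_mm * (a @ self.w)

    def radius_dz(self, a: np.ndarray) -> np.ndarray:
        return self.cfg.bulge_amplitude_mm * (a @ self.dw)

    def positions(self, a: np.ndarray) -> np.ndarray:
        r = self.radius(a)
        p = self.e_r * r[:, None]
        p[:, 2] = self.z
        return p

    def radial_rate(self, da: np.ndarray) -> np.ndarray:
        """Radial velocity (or acceleration) per vertex from activity derivative da."""
        return self.cfg.bulge_amplitude_mm * (da @ self.w)

    def strain_invariant(self, a: np.ndarray, a_ref: np.ndarray) -> np.ndarray:
        r, r_ref = self.radius(a), self.radius(a_ref)
        s, s_ref = self.radius_dz(a), self.radius_dz(a_ref)
        lam_th2 = (r / r_ref) ** 2
        lam_z2 = (1.0 + s**2) / (1.0 + s_ref**2)
        return 0.5 * (lam_th2 + lam_z2 - 2.0)


def add_noise(mesh: SurfaceMesh, sigma_mm: float, seed: int) -> SurfaceMesh:
    """I.i.d. isotropic Gaussian offset per vertex; topology/colors unchanged."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return mesh.with_vertices(mesh.vertices.copy())
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, sigma_mm, size=mesh.vertices.shape)
    return mesh.with_vertices(mesh.vertices + offsets)


def generate_sequence(config: SimConfig) -> SimSequence:
    """Generate a full deforming-tube sequence (deterministic given ``config.seed``)."""
    cfg = config
    field_ = _BulgeField(cfg)
    faces = _tube_topology(cfg.n_circumferential, cfg.n_axial)
    n_vertices = cfg.n_circumferential * cfg.n_axial

    colors = np.full((n_vertices, 3), _BASE_COLOR)
    marker_idx = _marker_vertex_indices(cfg)
    colors[marker_idx] = _DOT_COLOR

    a0 = np.zeros(cfg.n_muscles)
    template = SurfaceMesh(field_.positions(a0), faces, colors.copy())

    times = cfg.frame_times
    K = cfg.n_frames
    truth_pos = np.empty((K, n_vertices, 3))
    truth_vel = np.empty_like(truth_pos)
    truth_acc = np.empty_like(truth_pos)
    truth_inv = np.empty((K, n_vertices))
    da = field_.spline.derivative(1)
    dda = field_.spline.derivative(2)
    for k, t in enumerate(times):
        a_k = cfg.activity_profile[k]
        truth_pos[k] = field_.positions(a_k)
        truth_vel[k] = field_.e_r * field_.radial_rate(np.atleast_1d(da(t)))[:, None]
        truth_acc[k] = field_.e_r * field_.radial_rate(np.atleast_1d(dda(t)))[:, None]
        truth_inv[k] = field_.strain_invariant(a_k, a0)

    rng = np.random.default_rng(cfg.seed)
    frame_seeds = rng.integers(0, 2**31 - 1, size=K)
    targets = []
    for k in range(K):
        clean = SurfaceMesh(truth_pos[k].copy(), faces, colors.copy())
        targets.append(add_noise(clean, cfg.noise_sigma_mm, int(frame_seeds[k])))

    activity = ActivitySeries(cfg.activity_profile.copy(), times)
    return SimSequence(template, targets, truth_pos, truth_vel, truth_acc,
                       truth_inv, activity, marker_idx, cfg.seed, cfg)
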