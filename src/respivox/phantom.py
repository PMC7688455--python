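"""Synthetic breathing-torso phantom.

Generates what the two-depth-camera rig in a motion-tracking lab would see:
timestamped point clouds of a breathing thoracoabdominal surface, marker
trajectories sampled at fixed skin locations, and an internal tumor
trajectory that lags the surface (hysteresis) and may couple nonlinearly.

Geometry
--------
The torso at rest is the upper half of an axis-aligned ellipsoid with half
axes ``(a, b, c)`` (mm): body axis along x, lateral along y, anterior along
+z, the patient lying on the z=0 plane.  Surface locations are addressed by
the parameter pair ``(u, v) = (x/a, y/b)`` on the unit disk.  Breathing
displaces each surface point along its outward normal by

    ``delta(p, t) = surface_amplitude_max * a(u, v) * s(t)``

where ``a(u, v)`` is an isotropic Gaussian bump peaking (value 1) at
``amplitude_center`` — the spatially varying amplitude that makes markers at
different skin positions trace different motion ranges — and ``s(t)`` is a
periodic waveform in [0, 1].  The default waveform ``cos4``,
``s = cos^4(pi t / T)``, dwells near end-exhale as quiet human breathing
does; ``sinusoid`` selects ``s = (1 + cos(2 pi t / T)) / 2``.

The tumor moves along the body axis as
``x_T(t) = tumor_amplitude * g(s(t - lag))`` with ``g`` the identity, square
or cube per ``tumor_coupling`` and ``lag = tumor_phase_lag * T / (2 pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import FrameCloud
from .errors import ConfigurationError, DomainError

__all__ = [
    "PhantomConfig",
    "TumorTrajectory",
    "surface_waveform",
    "amplitude_field",
    "simulate_surface",
    "simulate_tumor",
    "sample_markers",
]

_WAVEFORMS = ("cos4", "sinusoid")
_COUPLINGS = ("linear", "quadratic", "cubic")


@dataclass
class PhantomConfig:
    """All knobs of the synthetic phantom; units are mm, s, Hz, radians.

    Defaults emulate one minute of quiet breathing of a small torso phantom
    sampled at 10 Hz: a 2 cm peak anterior excursion over the abdomen, a
    1 cm tumor excursion lagging the surface by 0.3 rad, millimeter-scale
    sensor noise and a few percent gross outliers.
    """

    torso_half_axes: tuple[float, float, float] = (150.0, 100.0, 80.0)
    breathing_period: float = 4.0
    n_frames: int = 600
    frame_rate: float = 10.0
    surface_amplitude_max: float = 20.0
    amplitude_center: tuple[float, float] = (0.3, 0.0)
    amplitude_width: float = 0.35
    tumor_amplitude: float = 10.0
    tumor_phase_lag: float = 0.3
    tumor_coupling: str = "linear"
    noise_sigma: float = 1.0
    outlier_fraction: float = 0.02
    point_density: int = 4000
    waveform: str = "cos4"
    seed: int = 0

    def __post_init__(self) -> None:
        axes = tuple(float(x) for x in self.torso_half_axes)
        if len(axes) != 3 or any(x <= 0 for x in axes):
            raise ConfigurationError(f"torso_half_axes must be 3 positive lengths, got {axes}")
        self.torso_half_axes = axes
        if self.breathing_period <= 0:
            raise ConfigurationError("breathing_period must be > 0")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be > 0")
        if self.surface_amplitude_max < 0:
            raise ConfigurationError("surface_amplitude_max must be >= 0")
        if not (0.0 <= self.outlier_fraction < 0.5):
            raise ConfigurationError("outlier_fraction must be in [0, 0.5)")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.point_density < 4:
            raise ConfigurationError("point_density must be >= 4")
        if self.amplitude_width <= 0:
            raise ConfigurationError("amplitude_width must be > 0")
        if self.waveform not in _WAVEFORMS:
            raise ConfigurationError(f"waveform must be one of {_WAVEFORMS}, got {self.waveform!r}")
        if self.tumor_coupling not in _COUPLINGS:
            raise ConfigurationError(
                f"tumor_coupling must be one of {_COUPLINGS}, got {self.tumor_coupling!r}"
            )
        u0, v0 = self.amplitude_center
        if u0 * u0 + v0 * v0 > 1.0:
            raise ConfigurationError("amplitude_center must lie inside the unit uv disk")

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return np.arange(self.n_frames, dtype=float) / self.frame_rate


@dataclass
class TumorTrajectory:
    """Internal tumor path: strictly increasing times (s), 3D positions (mm)."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def principal(self) -> np.ndarray:
        """Displacement along the dominant motion axis (largest variance)."""
        centered = self.positions - self.positions.mean(axis=0)
        axis = int(np.argmax(centered.var(axis=0)))
        return self.positions[:, axis]


def surface_waveform(config: PhantomConfig, t: np.ndarray) -> np.ndarray:
    """Periodic breathing waveform s(t) in [0, 1]."""
    t = np.asarray(t, dtype=float)
    T = config.breathing_period
    if config.waveform == "cos4":
        return np.cos(np.pi * t / T) ** 4
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * t / T))


def amplitude_field(config: PhantomConfig, uv: np.ndarray) -> np.ndarray:
    """Spatial amplitude a(u, v): Gaussian bump, 1 at amplitude_center."""
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    d2 = ((uv - np.asarray(config.amplitude_center)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * config.amplitude_width**2))


def _base_surface(config: PhantomConfig, uv: np.ndarray):
    """Rest-state surface points and unit outward normals at parameters uv."""
    a, b, c = config.torso_half_axes
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    r2 = (uv**2).sum(axis=1)
    if np.any(r2 > 1.0 + 1e-12):
        bad = uv[np.argmax(r2)]
        raise DomainError(f"uv location {tuple(bad)} outside the unit-disk torso domain")
    w = np.sqrt(np.clip(1.0 - r2, 0.0, None))
    pts = np.column_stack([a * uv[:, 0], b * uv[:, 1], c * w])
    # outward ellipsoid normal: grad of (x/a)^2+(y/b)^2+(z/c)^2
    n = np.column_stack([uv[:, 0] / a, uv[:, 1] / b, w / c])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return pts, n


def _sample_uv(config: PhantomConfig) -> np.ndarray:
    """Quasi-uniform lattice sample of the half-ellipsoid in uv coordinates.

    A Fibonacci spiral on the upper unit hemisphere (cos-uniform in height,
    golden-angle azimuth) emulates the regular pixel raster of a structured
    light depth camera: near-constant point spacing with no Poisson gaps,
    and the steep rim as well covered as the dome top.
    """
    n = config.point_density
    i = np.arange(n, dtype=float)
    z = (i + 0.5) / n
    phi = i * (np.pi * (3.0 - np.sqrt(5.0)))  # golden angle
    rxy = np.sqrt(1.0 - z * z)
    return np.column_stack([rxy * np.cos(phi), rxy * np.sin(phi)])


def deformed_surface(config: PhantomConfig, uv: np.ndarray, s: float) -> np.ndarray:
    """Noise-free deformed surface at breathing state s (analytic field)."""
    base, normals = _base_surface(config, uv)
    amp = amplitude_field(config, uv)
    return base + normals * (config.surface_amplitude_max * amp * s)[:, None]


def simulate_surface(config: PhantomConfig) -> list[FrameCloud]:
    """Generate the n_frames breathing point-cloud sequence.

    The rest-state sample of surface locations is drawn once per sequence
    (the simulated sensor re-observes the same physical patch); per-frame
    Gaussian noise and uniform-box outliers are drawn independently.
    Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    uv = _sample_uv(config)
    base, normals = _base_surface(config, uv)
    amp = amplitude_field(config, uv) * config.surface_amplitude_max
    s = surface_waveform(config, config.times)

    # outlier box: 1.5x inflated AABB of the full motion envelope
    lo = base.min(axis=0)
    hi = (base + normals * amp[:, None]).max(axis=0)
    center, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    box_lo, box_hi = center - 1.5 * half, center + 1.5 * half

    n_out = int(round(config.outlier_fraction * config.point_density))
    frames: list[FrameCloud] = []
    for i, (t, si) in enumerate(zip(config.times, s)):
        pts = base + normals * (amp * si)[:, None]
        if config.noise_sigma > 0:
            pts = pts + rng.normal(0.0, config.noise_sigma, pts.shape)
        if n_out > 0:
            idx = rng.choice(config.point_density, n_out, replace=False)
            pts = pts.copy() if pts is base else pts
            pts[idx] = rng.uniform(box_lo, box_hi, (n_out, 3))
        frames.append(FrameCloud(points=pts, frame_index=i, time=float(t)))
    return frames


def simulate_tumor(config: PhantomConfig, depth: float = 60.0) -> TumorTrajectory:
    """Internal tumor trajectory on the surface-frame timestamps.

    The tumor sits ``depth`` mm below the torso mid-plane origin and
    translates along the body axis (x, the dominant superior-inferior
    direction of real lung/liver tumors) by
    ``tumor_amplitude * g(s(t - lag))``.
    """
    t = config.times
    lag = config.tumor_phase_lag * config.breathing_period / (2.0 * np.pi)
    s = surface_waveform(config, t - lag)
    if config.tumor_coupling == "linear":
        g = s
    elif config.tumor_coupling == "quadratic":
        g = s**2
    else:
        g = s**3
    x = config.tumor_amplitude * g
    positions = np.column_stack([x, np.zeros_like(x), np.full_like(x, -depth)])
    return TumorTrajectory(times=t, positions=positions)


def sample_markers(
    config: PhantomConfig,
    marker_uv: np.ndarray,
    noise_sigma: float | None = None,
) -> np.ndarray:
    """Trajectories of skin markers at fixed uv locations.

    Positions come from the analytic noiseless deformation field evaluated
    on the frame timestamps; ``noise_sigma`` (mm), if given, adds isotropic
    Gaussian tracking noise (seeded independently of the surface sample so
    markers and clouds are uncorrelated noise-wise).

    Returns an (n_markers, n_frames, 3) array.
    """
    marker_uv = np.atleast_2d(np.asarray(marker_uv, dtype=float))
    base, normals = _base_surface(config, marker_uv)  # raises DomainError outside disk
    amp = amplitude_field(config, marker_uv) * config.surface_amplitude_max
    s = surface_waveform(config, config.times)
    traj = base[:, None, :] + normals[:, None, :] * (amp[:, None] * s[None, :])[:, :, None]
    if noise_sigma:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6D61726B]))
        traj = traj + rng.normal(0.0, noise_sigma, traj.shape)
    return traj
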