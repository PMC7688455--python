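"""Shared fixtures: small geometric clouds and a desk-scale phantom run."""

import numpy as np
import pytest

from respivox import FrameCloud, PhantomConfig, PipelineConfig, characterize


def fibonacci_sphere(n: int, radii=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Quasi-uniform closed ellipsoid sample (no boundary)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * (np.pi * (3.0 - np.sqrt(5.0)))
    r = np.sqrt(1.0 - z * z)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts * np.asarray(radii)


def fibonacci_dome(n: int, radii=(80.0, 60.0, 50.0)) -> np.ndarray:
    """Quasi-uniform open hemisphere patch (rim at z = 0)."""
    i = np.arange(n, dtype=float)
    z = (i + 0.5) / n
    phi = i * (np.pi * (3.0 - np.sqrt(5.0)))
    r = np.sqrt(1.0 - z * z)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts * np.asarray(radii)


def planar_grid(nx: int = 12, ny: int = 12, spacing: float = 1.0) -> np.ndarray:
    x, y = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing, indexing="ij")
    return np.column_stack([x.ravel(), y.ravel(), np.zeros(nx * ny)])


@pytest.fixture
def grid_cloud() -> FrameCloud:
    return FrameCloud(points=planar_grid())


@pytest.fixture
def dome_cloud() -> FrameCloud:
    return FrameCloud(points=fibonacci_dome(3000))


def quick_phantom(**overrides) -> PhantomConfig:
    """Small, fast phantom used across tests (seconds, not minutes)."""
    defaults = dict(
        torso_half_axes=(100.0, 70.0, 50.0),
        breathing_period=4.0,
        n_frames=80,
        frame_rate=5.0,
        surface_amplitude_max=15.0,
        tumor_amplitude=8.0,
        point_density=1500,
        noise_sigma=1.0,
        outlier_fraction=0.02,
        seed=0,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


def quick_pipeline_config(**phantom_overrides) -> PipelineConfig:
    return PipelineConfig(
        phantom=quick_phantom(**phantom_overrides),
        resolution=8.0,
        lle_k=10,
        lle_d=6,
    )


@pytest.fixture(scope="session")
def quick_run():
    """One desk-scale end-to-end characterization, shared by feature tests."""
    return characterize(
        PipelineConfig(
            phantom=PhantomConfig(
                torso_half_axes=(100.0, 70.0, 50.0),
                n_frames=80,
                frame_rate=5.0,
                surface_amplitude_max=15.0,
                tumor_amplitude=8.0,
                point_density=1500,
                noise_sigma=1.0,
                outlier_fraction=0.02,
                seed=0,
            ),
            resolution=8.0,
            lle_k=10,
            lle_d=6,
        )
    )
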