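import numpy as np
import pytest

from ependypol import synthetic_scene as ss


@pytest.fixture(scope="session")
def wt_mosaic():
    """A coordinated (wild-type-like) mosaic shared across tests."""
    cfg = ss.SceneConfig(n_cells=200, seed=11)
    labels, bb, feet, truth = ss.generate_mosaic(cfg)
    return cfg, labels, bb, feet, truth


@pytest.fixture(scope="session")
def mutant_mosaic():
    """A disorganized (mutant-like) mosaic: kappa = 0, small offset."""
    cfg = ss.SceneConfig.mutant(seed=12)
    labels, bb, feet, truth = ss.generate_mosaic(cfg)
    return cfg, labels, bb, feet, truth


@pytest.fixture(scope="session")
def coherent_video():
    """Noise-free coherent flow video with ground truth."""
    cfg = ss.FlowConfig(regime="coherent", mean_direction=45.0,
                        diffusion_px=0.0, n_particles=40, n_frames=50,
                        seed=13)
    frames, truth = ss.generate_flow_video(cfg)
    return cfg, frames, truth


def random_convex_polygon(rng: np.random.Generator, n_vertices: int = 7,
                          radius: float = 10.0) -> np.ndarray:
    """A random convex polygon: points on a circle with jittered radii,
    sorted by angle (convex for modest jitter)."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    r = radius * rng.uniform(0.7, 1.0, n_vertices)
    center = rng.uniform(5, 20, 2)
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])
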