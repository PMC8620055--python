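import numpy as np
import pytest

from glom3d.phantom import PhantomSpec, generate_phantom
from glom3d.pipeline import PipelineConfig, run_pipeline


def voxelized_ball(radius_um: float, spacing, pad: int = 4) -> np.ndarray:
    """Boolean mask of a solid ball: voxel centers within radius of the origin."""
    spacing = np.asarray(spacing, dtype=float)
    extents = [int(np.ceil(2 * radius_um / s)) + pad for s in spacing]
    axes = [(np.arange(n) - n / 2 + 0.5) * s for n, s in zip(extents, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return zz**2 + yy**2 + xx**2 <= radius_um**2


@pytest.fixture(scope="session")
def default_phantom():
    spec = PhantomSpec(seed=1)
    stack, truth = generate_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def default_result(default_phantom):
    _, stack, _ = default_phantom
    return run_pipeline(stack, PipelineConfig())


@pytest.fixture(scope="session")
def small_phantom_runs():
    """Pipeline runs on a 5-seed suite of reduced phantoms (for monotonicity)."""
    runs = []
    for seed in range(1, 6):
        spec = PhantomSpec(
            shape=(40, 160, 160),
            glomerulus_count=10,
            glomerulus_radius=(6.0, 0.5),
            tubule_count=150,
            large_tube_count=2,
            seed=seed,
        )
        stack, truth = generate_phantom(spec)
        runs.append((spec, truth, run_pipeline(stack, PipelineConfig())))
    return runs
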