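import numpy as np
import pytest
from hypothesis import settings

import bovitherm as bt

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def quantized_scene():
    """Noise-free scene whose patch albedos map to exact integer gray levels.

    At base gray 200 and snow reference 0.85, albedo a renders at
    200 * a / 0.85, which is integral for a in {0.68, 0.425, 0.0425}
    (160, 100, 10 gray levels), so the ratio estimator inverts exactly.
    """
    spec = bt.SceneSpec(
        snow_gray=200,
        patches=(
            bt.PatchSpec("white", 0.68, 20, 20, 60, 60),
            bt.PatchSpec("red", 0.425, 120, 20, 60, 60),
            bt.PatchSpec("black", 0.0425, 220, 20, 60, 60),
        ),
        noise_sd=0.0,
        seed=0,
    )
    image, masks, truth = bt.generate_winter_image(spec)
    return spec, image, masks, truth


@pytest.fixture
def model_mode_data():
    """Merged analysis table from the default model-mode generator (noisy)."""
    obs, cov, truth = bt.generate_thermal_observations(
        bt.ThermalGenParams(n=638, noise_sd=5.0, seed=11)
    )
    return bt.assemble_dataset(obs, cov), truth


@pytest.fixture
def slope_mode_data():
    """Merged analysis table from the slope-mode generator."""
    obs, cov, truth = bt.generate_thermal_observations(
        bt.ThermalGenParams(n=600, mode="slope", noise_sd=3.0, seed=7)
    )
    return bt.assemble_dataset(obs, cov), truth


def seeds_from(base: int, count: int) -> list[int]:
    """Deterministic per-replicate seeds derived from one base seed."""
    return [int(s & 0x7FFFFFFF) for s in np.random.SeedSequence(base).generate_state(count)]
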