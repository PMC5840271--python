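import numpy as np
import pytest

import topouptake as tu


LINE_VALUES = [5.0, 1.0, 4.0, 2.0, 3.0]


@pytest.fixture
def line_array() -> np.ndarray:
    """The 5-voxel line with values [5, 1, 4, 2, 3] and zeros elsewhere."""
    arr = np.zeros((1, 1, 5))
    arr[0, 0, :] = LINE_VALUES
    return arr


@pytest.fixture
def line_tree(line_array):
    return tu.build_merge_tree(line_array, terminal_value=0.0)


def random_positive_array(seed: int, shape=(5, 5, 5)) -> np.ndarray:
    """Random array with distinct positive values (generic inputs for the sweep)."""
    rng = np.random.default_rng(seed)
    vals = rng.permutation(np.arange(1, np.prod(shape) + 1, dtype=float))
    return (vals + rng.uniform(0.01, 0.99, size=vals.size)).reshape(shape)


def small_phantom_params(seed: int) -> "tu.PhantomParams":
    """A small, fast phantom configuration for structural tests."""
    return tu.PhantomParams(
        shape=(14, 14, 14),
        semi_axes=(5.0, 4.5, 4.0),
        n_bumps=8,
        n_shell_bumps=2,
        seed=seed,
    )


def small_phantom_function(seed: int) -> "tu.IntensityFunction":
    """One processed (decay-corrected, smoothed, masked) small phantom image."""
    params = small_phantom_params(seed)
    rng_a = np.random.default_rng([seed, 0])
    rng_n = np.random.default_rng([seed, 1])
    image, roi, _ = tu.generate_phantom(params, "S1", 1, 24.0, rng_a, rng_n)
    img = tu.gaussian_smooth(tu.decay_correct(image))
    return tu.apply_roi(img, roi)


@pytest.fixture
def phantom_function():
    return small_phantom_function(7)


@pytest.fixture
def default_cohort():
    return tu.generate_cohort(tu.PhantomParams(seed=11))
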