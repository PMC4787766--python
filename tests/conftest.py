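import numpy as np
import pytest

from pip3scope.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    cfg = GeneratorConfig(n_genes=400, seed=11)
    return generate_dataset(cfg)


def hierarchical_profiles(c: int, n: int = 120, d: int = 18, noise: float = 0.5, seed: int = 0):
    """Gene profiles drawn around c cluster centres with geometrically
    decreasing separations, so that merging below c is unambiguous and
    every k <= c admits a stable clustering."""
    rng = np.random.default_rng(seed)
    dirs = np.linalg.qr(rng.normal(size=(d, d)))[0].T
    if c == 2:
        centers = np.array([6 * dirs[0], -6 * dirs[0]])
    elif c == 3:
        centers = np.array(
            [6 * dirs[0], -6 * dirs[0] + 3 * dirs[1], -6 * dirs[0] - 3 * dirs[1]]
        )
    elif c == 4:
        centers = np.array(
            [
                6 * dirs[0] + 3 * dirs[1],
                6 * dirs[0] - 3 * dirs[1],
                -6 * dirs[0] + 1.8 * dirs[2],
                -6 * dirs[0] - 1.8 * dirs[2],
            ]
        )
    else:
        raise ValueError("c must be 2, 3 or 4")
    labels = np.arange(n) % c
    X = centers[labels] + rng.normal(0, noise, size=(n, d))
    return X, labels
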