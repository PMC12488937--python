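import numpy as np
import pytest

from organoid_qc.synthgen import (
    CohortConfig,
    cohort_truth_table,
    generate_cohort,
    generate_fluorescence_panel,
)


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    cohort = generate_cohort(default_config)
    generate_fluorescence_panel(cohort, seed=default_config.seed + 3)
    return cohort


@pytest.fixture(scope="session")
def truth_table(default_cohort):
    return cohort_truth_table(default_cohort)


@pytest.fixture(scope="session")
def separated_config():
    """High class separation (>= 4 SD on log-Feret) for known-truth clustering."""
    return CohortConfig(
        feret_um_dist_high=(2400.0, 0.11),
        feret_um_dist_low=(3800.0, 0.11),
        seed=7,
    )


@pytest.fixture(scope="session")
def separated_table(separated_config):
    return cohort_truth_table(generate_cohort(separated_config))


def random_blob_mask(rng: np.random.Generator, size: int = 48) -> np.ndarray:
    """Random connected fat blob: union of discs around a random walk."""
    from skimage.draw import disk

    mask = np.zeros((size, size), dtype=bool)
    r, c = size // 2, size // 2
    for _ in range(rng.integers(3, 9)):
        rad = int(rng.integers(4, size // 4))
        rr, cc = disk((r, c), rad, shape=mask.shape)
        mask[rr, cc] = True
        r = int(np.clip(r + rng.integers(-size // 5, size // 5 + 1), rad, size - rad - 1))
        c = int(np.clip(c + rng.integers(-size // 5, size // 5 + 1), rad, size - rad - 1))
    return mask
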