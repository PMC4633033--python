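import numpy as np
import pytest

from bmiconn.structural import Atlas, FiberSet, Region
from bmiconn.synthetic import SyntheticSpec


@pytest.fixture
def small_atlas() -> Atlas:
    """Six regions with fixed areas; regions 0 and 3 are reward-flagged."""
    areas = [100.0, 200.0, 150.0, 120.0, 180.0, 90.0]
    return Atlas(
        [
            Region(i, f"R{i}", a, reward_flag=(i in (0, 3)))
            for i, a in enumerate(areas)
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_fiber_set(rng: np.random.Generator, n_regions: int, n_fibers: int, subject="s0") -> FiberSet:
    u = rng.integers(0, n_regions, n_fibers)
    v = rng.integers(0, n_regions, n_fibers)
    shift = (u == v)
    v = np.where(shift, (v + 1) % n_regions, v)
    lengths = rng.uniform(5.0, 600.0, n_fibers)
    return FiberSet(subject, u, v, lengths)


def powered_spec(seed: int = 0, n_per_group: int = 30) -> SyntheticSpec:
    """Small cohort with strong planted effects: every stage of the pipeline
    produces non-empty output quickly (used for pipeline/CLI tests)."""
    return SyntheticSpec(
        n_per_group=n_per_group,
        n_regions=10,
        planted_edges=[(0, 4, 2.5), (3, 7, 2.2), (0, 8, 2.4)],
        coupling_edges=[((0, 4), 0, 0.6), ((3, 7), 3, 0.55), ((0, 8), 8, 0.5)],
        bmi_driver_features=[("sc:0-4", 1.0), ("fc:0", 0.8)],
        noise_sd=0.7,
        edge_sparsity=0.2,
        n_timepoints=256,
        seed=seed,
    )
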