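import numpy as np
import pytest

from skelstats import MetricStack, SkeletonSpace


@pytest.fixture
def cube_space() -> SkeletonSpace:
    """Fully masked 5x5x5 grid (125 skeleton columns)."""
    return SkeletonSpace(mask=np.ones((5, 5, 5), dtype=bool))


@pytest.fixture
def flat_space() -> SkeletonSpace:
    """500-column skeleton inside an 8x8x8 grid, C-order leading block."""
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask.ravel()[:500] = True
    return SkeletonSpace(mask=mask)


def make_stack(space: SkeletonSpace, n: int, rng: np.random.Generator) -> MetricStack:
    """Pure-noise FA stack on a space."""
    data = np.clip(0.5 + 0.08 * rng.standard_normal((n, space.n_columns)), 0.01, 0.99)
    return MetricStack("FA", data, np.arange(n), space)
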