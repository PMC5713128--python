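import numpy as np
import pytest

from quatdba.synthetic_data import (
    PerturbationModel,
    builtin_kick_specs,
    canonical_skeleton,
    make_action_instance,
)


def random_unit_quats(rng: np.random.Generator, n: int) -> np.ndarray:
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def skeleton():
    return canonical_skeleton()


@pytest.fixture(scope="session")
def kick_specs():
    return builtin_kick_specs()


@pytest.fixture
def clean_recording(kick_specs):
    """A noise-free mae-like take (exact slerp trajectory)."""
    return make_action_instance(kick_specs[2], PerturbationModel.none(), np.random.default_rng(0))


def brute_force_dtw(cost: np.ndarray) -> float:
    """Independent DTW oracle: exhaustive enumeration of all admissible
    monotone boundary-to-boundary paths (exponential; n, m <= 6 only)."""
    n, m = cost.shape
    best = [np.inf]

    def walk(i, j, total):
        total += cost[i, j]
        if total >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = total
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, total)
        if j + 1 < m:
            walk(i, j + 1, total)
        if i + 1 < n:
            walk(i + 1, j, total)
    walk(0, 0, 0.0)
    return best[0]
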