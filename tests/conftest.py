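import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_system():
    """A 6-ROI system with distinct, well-separated conjugate pairs."""
    from neuromodes import make_stable_system

    spec = [(0.85, 0.4, 1), (0.9, 1.1, 1), (0.8, 2.0, 1)]
    return make_stable_system(6, spec, seed=7)


@pytest.fixture(scope="session")
def driven_panel(small_system):
    """A noisy task run with planted sparse inputs plus its ground truth."""
    from neuromodes import make_sparse_inputs, simulate_run

    rng = np.random.default_rng(3)
    B = rng.standard_normal((6, 2))
    B /= np.linalg.norm(B, axis=0)
    U = make_sparse_inputs(2, 40, 0.1, 1.0, seed=4)
    panel = simulate_run(small_system, 40, B_true=B, U=U, noise_sd=0.02, seed=5)
    return panel, B, U


def assert_eigenvalues_match(actual, expected, tol=1e-8):
    """Multiset comparison of complex spectra via optimal matching."""
    from scipy.optimize import linear_sum_assignment

    actual = np.asarray(actual)
    expected = np.asarray(expected)
    assert actual.shape == expected.shape
    cost = np.abs(actual[:, None] - expected[None, :])
    r, c = linear_sum_assignment(cost)
    assert cost[r, c].max() < tol, f"spectra differ by {cost[r, c].max():.3g}"
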