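import numpy as np
import pytest

from msot import MsotConfig, SkeletonSpec, make_branching_snapshot


@pytest.fixture(scope="session")
def four_arm():
    """Default four-arm branching snapshot (400 cells) with ground truth."""
    return make_branching_snapshot(SkeletonSpec())


@pytest.fixture(scope="session")
def small_four_arm():
    """A reduced four-arm snapshot for fast pipeline tests."""
    spec = SkeletonSpec(n_cells=150, n_initial=4, n_terminal_per_arm=3, seed=2)
    return make_branching_snapshot(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def fast_config():
    """Small-instance solver configuration with tight tolerance."""
    return MsotConfig(T=4, epsilon_start=0.05, prox_iters=5, tol_tau=1e-5)
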