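import numpy as np
import pytest

import neurorf as nr


@pytest.fixture(scope="session")
def task_grid() -> nr.Grid1D:
    """The 100 ms @ 2 kHz grid used by the timeseries tasks (d = 200)."""
    return nr.default_task_grid()


@pytest.fixture(scope="session")
def small_grid() -> nr.Grid1D:
    """A cheap 1-D grid: 50 ms at 1 kHz (d = 50, harmonic spacing 20 Hz)."""
    return nr.Grid1D(n_samples=50, dt_ms=1.0)


@pytest.fixture(scope="session")
def small_grid2d() -> nr.Grid2D:
    return nr.Grid2D(8, 8)


@pytest.fixture(scope="session")
def sensilla_cov(small_grid) -> nr.CovarianceModel:
    """A sensilla covariance with passband [40, 160] Hz, gamma 20 ms."""
    return nr.build_sensilla_cov(small_grid, nr.SensillaParams(40, 160, 20))


@pytest.fixture(scope="session")
def v1_cov(small_grid2d) -> nr.CovarianceModel:
    return nr.build_v1_cov(
        small_grid2d, nr.V1Params(2.0, 1.0, small_grid2d.center)
    )


@pytest.fixture(scope="session")
def identity_cov(small_grid) -> nr.CovarianceModel:
    return nr.build_null_cov("unstructured", small_grid)


def random_psd(d: int, rank: int, seed: int) -> np.ndarray:
    """A random PSD matrix of known rank built from explicit factors."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((d, rank))
    return A @ A.T
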