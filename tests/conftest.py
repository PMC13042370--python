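import numpy as np
import pytest

from ecohyst import ModelParams, SyntheticConfig, generate_loop, generate_one_sided

#: state-noise level used across noisy-data tests: 2% of the normalized range
NOISE_SD = 0.02 * (np.e - 1.0)


@pytest.fixture(scope="session")
def norm9() -> ModelParams:
    """Standardized hysteretic model: C0 = 1, C1 = e, K = 9."""
    return ModelParams.normalized(9.0)


@pytest.fixture(scope="session")
def loop9(norm9):
    """Noiseless full loop traced from the K = 9 standardized model."""
    return generate_loop(SyntheticConfig(params=norm9, n_per_branch=50, seed=1))


@pytest.fixture(scope="session")
def forward9(norm9):
    """Noiseless forward-only sweep plus its true pre-jump index."""
    return generate_one_sided(
        SyntheticConfig(params=norm9, n_per_branch=50, seed=3), "forward"
    )


def grid_scan_extrema(params: ModelParams, n: int = 10_000) -> np.ndarray:
    """Brute-force oracle: states of interior extrema of f from a dense scan.

    Independent of the analytic tipping-point path: evaluates f on a grid
    and reports sign changes of the finite differences.
    """
    ys = np.linspace(params.c0 + 1e-9, params.c1 - 1e-6 * (params.c1 - params.c0), n)
    fs = (ys - params.c0) / (params.c1 - ys) * np.exp(params.k / ys)
    sign = np.sign(np.diff(fs))
    change = np.flatnonzero(np.diff(sign) != 0)
    return ys[change + 1]
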