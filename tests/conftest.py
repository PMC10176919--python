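import numpy as np
import pytest

from bbumfit import run_benchmark

# Heavy simulation fixtures are session-scoped so every consumer shares one run.
N_SIMS = 500
CAL_SIMS = 250
ALPHA_GRID = (0.2, 0.1, 0.05, 0.02, 0.01, 0.005)


@pytest.fixture(scope="session")
def bench_no_outliers():
    """500 no-outlier simulations scored by all three methods at alpha=0.05."""
    return run_benchmark(N_SIMS, alphas=(0.05,), outliers=False, seed=11)


@pytest.fixture(scope="session")
def bench_outliers():
    """500 outlier-containing simulations scored by all three methods."""
    return run_benchmark(N_SIMS, alphas=(0.05,), outliers=True, seed=12)


@pytest.fixture(scope="session")
def bench_calibration():
    """250 no-outlier simulations scored by both BBUM variants over the alpha grid."""
    return run_benchmark(
        CAL_SIMS,
        methods=("bbum_original", "bbum_modified"),
        alphas=ALPHA_GRID,
        outliers=False,
        seed=13,
        n_boot=1000,
    )


def summary_row(result, method, alpha=None):
    s = result.summary
    if alpha is None:
        row = s[s["method"] == method]
    else:
        row = s[(s["method"] == method) & (np.isclose(s["alpha"], alpha))]
    assert len(row) == 1, f"expected one summary row for {method}/{alpha}"
    return row.iloc[0]
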