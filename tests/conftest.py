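import numpy as np
import pytest

from dime import synthetic
from dime.core import DimeConfig, run_dime

# Light configuration used in tests: fewer restarts and a narrower k range
# than the library defaults, chosen to keep the planted benchmarks fast while
# leaving the recovered structure unchanged.
BENCH = DimeConfig(n_restarts=10, n_runs_consensus=10, k_max=6)
JACK = DimeConfig(n_restarts=3, n_runs_consensus=8, k_max=4)


@pytest.fixture(scope="session")
def bench():
    """Two-module planted benchmark: (immunome, ground truth, diseases)."""
    return synthetic.benchmark_instance(seed=1)


@pytest.fixture(scope="session")
def bench_result(bench):
    imm, gt, net = bench
    return run_dime(imm, net, "D1", seed=1, config=BENCH)


@pytest.fixture(scope="session")
def small_immunome():
    from dime.io import ImmunomeMatrix

    rng = np.random.default_rng(0)
    return ImmunomeMatrix(
        [f"g{i}" for i in range(6)],
        [f"c{j}" for j in range(4)],
        rng.uniform(0, 8, size=(6, 4)),
    )
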