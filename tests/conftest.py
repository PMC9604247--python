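import numpy as np
import pytest

import methylseg as ms

ACCEPTANCE_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def default_sim_runs():
    """Default-condition synthetic methylomes (~50k sites) for several seeds."""
    return {
        seed: ms.simulate(ms.SimulationConfig(seed=seed)) for seed in ACCEPTANCE_SEEDS
    }


@pytest.fixture(scope="session")
def fitted_k3(default_sim_runs):
    """K=3 model trained at d0=1250 on the first default synthetic run."""
    res = default_sim_runs[ACCEPTANCE_SEEDS[0]]
    return ms.fit(res.series, K=3, d0=1250.0, seed=ACCEPTANCE_SEEDS[0])


@pytest.fixture
def toy_table():
    """Five CpGs on one chromosome with depths 1, 4, 8, 9, 12."""
    return ms.MethylomeTable.from_arrays(
        chrom=["chr1"] * 5,
        pos=[100, 200, 300, 400, 500],
        meth=[1, 2, 4, 3, 6],
        unmeth=[0, 2, 4, 6, 6],
        sample_id="toy",
    )


@pytest.fixture
def small_series():
    rng = np.random.default_rng(7)
    pos = np.cumsum(rng.integers(10, 400, size=10))
    depth = rng.integers(1, 6, size=10)
    meth = rng.binomial(depth, 0.4)
    return ms.ObservationSeries(pos, meth, depth, chrom="chr1")
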