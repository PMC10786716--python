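import numpy as np
import pytest

import bridgeprs as bp


@pytest.fixture(scope="session")
def small_world():
    """A fast two-population world for structural tests."""
    cfg = bp.SimConfig(n_pop1=3000, n_pop2=1500, n_blocks=20, block_size=10,
                       splits_pop1=(2000, 500, 500),
                       splits_pop2=(500, 500, 500), seed=1)
    return bp.make_world(cfg)


@pytest.fixture(scope="session")
def small_run(small_world):
    """Full pipeline result on the fast world."""
    return bp.run_pipeline(small_world)


@pytest.fixture(scope="session")
def portability_runs():
    """Validation R^2 of the pipeline across 10 seeded replicates of the
    canonical desk-scale study design, with and without the causal variants
    present in the analyzed data."""
    out = []
    for seed in range(1, 11):
        world = bp.make_world(bp.default_small_world(seed=seed))
        with_causal = bp.run_pipeline(world).r2
        without_causal = bp.run_pipeline(bp.drop_causal(world)).r2
        out.append({"with": with_causal, "without": without_causal})
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
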