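import numpy as np
import pandas as pd
import pytest

import grnjdr as g


@pytest.fixture(scope="session")
def small_factors() -> g.LatentFactors:
    return g.simulate_latent_factors(n_samples=60, k_true=3, seed=11)


@pytest.fixture(scope="session")
def tiny_priors() -> tuple[g.MotifPrior, g.PpiPrior]:
    return g.simulate_priors(n_tfs=6, n_genes=15, motif_density=0.4,
                             ppi_density=0.2, seed=2)


@pytest.fixture(scope="session")
def small_cohort() -> g.SyntheticCohort:
    cfg = g.SimulationConfig(
        n_samples=60,
        block_features=(60, 40, 80),
        n_tfs=12,
        n_genes=60,
        seed=13,
    )
    return g.simulate_cohort(cfg)


@pytest.fixture
def random_block() -> g.OmicsBlock:
    rng = np.random.default_rng(5)
    vals = pd.DataFrame(
        rng.standard_normal((20, 15)),
        index=[f"f{i}" for i in range(20)],
        columns=[f"s{i}" for i in range(15)],
    )
    return g.OmicsBlock("random", vals)
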