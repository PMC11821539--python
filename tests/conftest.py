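import numpy as np
import pytest

from vlptools import ActivitySimSpec, simulate_activity


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def block_spec(groups=("WT", "cKO"), n=4, k=6, r_within=0.8, seed=0,
               r_per_group=None):
    """Small activity design: one k-region area with within-block correlation."""
    regions = [f"R{i}" for i in range(k)]
    sigmas = {}
    for gi, g in enumerate(groups):
        r = r_within if r_per_group is None else r_per_group[gi]
        sigma = np.full((k, k), r)
        np.fill_diagonal(sigma, 1.0)
        sigmas[g] = sigma
    means = {g: np.full(k, 500.0) for g in groups}
    return ActivitySimSpec(
        groups=list(groups), n_per_group=n, regions=regions,
        region_groups={r: "AREA" for r in regions},
        sigma_per_group=sigmas, mean_per_group=means, noise_sd=50.0, seed=seed)


@pytest.fixture
def small_table():
    return simulate_activity(block_spec(n=6, seed=7))
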