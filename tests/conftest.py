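import numpy as np
import pandas as pd
import pytest

from clonetrial.synthetic_trial import SimulationParams, TrialDesign, simulate_trial


def make_single_site(
    n_clones=6, n_blocks=3, n_ramets=2, sigma_c2=1.0, sigma_e2=1.0, seed=0,
    mean=10.0, block_sd=0.0,
):
    """One balanced single-site trial at one trait-age."""
    design = TrialDesign(
        site_ids=["S1"],
        blocks_per_site={"S1": n_blocks},
        ramets_per_plot={"S1": n_ramets},
        clone_ids=[f"C{i:02d}" for i in range(n_clones)],
        ages=[5],
    )
    params = SimulationParams(
        trait_means={("height", 5): mean},
        sigma_c2=sigma_c2,
        sigma_e2=sigma_e2,
        block_sd=block_sd,
        seed=seed,
    )
    return simulate_trial(design, params)


def make_multi_site(
    n_clones=16, sigma_c2=1.0, sigma_cs2=0.5, sigma_e2=4.0, seed=0, ages=(5,),
    site_spread=0.0,
):
    """Three-site trial with the reference block/plot layout."""
    design = TrialDesign.reference(n_clones=n_clones, ages=ages)
    site_effects = {}
    if site_spread:
        for i, s in enumerate(design.site_ids):
            for a in ages:
                site_effects[(s, "height", a)] = site_spread * (i - 1)
    params = SimulationParams(
        trait_means={("height", a): 10.0 for a in ages},
        site_effects=site_effects,
        sigma_c2=sigma_c2,
        sigma_cs2=sigma_cs2,
        sigma_e2=sigma_e2,
        seed=seed,
    )
    return simulate_trial(design, params)


@pytest.fixture(scope="session")
def single_site_data():
    data, truth = make_single_site(seed=11)
    return data, truth


@pytest.fixture(scope="session")
def multi_site_data():
    data, truth = make_multi_site(seed=7)
    return data, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric_distance(rng, n, labels=None):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    labels = labels or [f"s{i}" for i in range(n)]
    return pd.DataFrame(a, index=labels, columns=labels)
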