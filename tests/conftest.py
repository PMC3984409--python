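import numpy as np
import pytest

from psfscreen.data_model import OTUTable, PotMetadata
from psfscreen.synthetic import SyntheticConfig, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_table(rng, n=12, m=30, group="bacteria", trial_id="T01"):
    values = rng.gamma(2.0, 50.0, size=(n, m))
    values[values < 10] = 0.0
    # guarantee every row keeps a positive entry
    values[:, 0] += 1.0
    return OTUTable(
        sample_ids=[f"p{i:02d}" for i in range(n)],
        otu_ids=[f"OTU{j:03d}" for j in range(m)],
        values=values,
        group=group,
        trial_id=trial_id,
    )


@pytest.fixture
def small_trial():
    """One fast synthetic trial: 20 pots, 60 OTUs per group."""
    cfg = SyntheticConfig(
        n_trials=1, n_pots_per_cell=5, n_otus=60, frac_affinity=0.1, frac_effect=0.1, seed=7
    )
    return generate_trial(cfg, 0)


@pytest.fixture
def forty_pot_trial():
    """A trial at the real study's 40-pot design, reduced OTU count."""
    cfg = SyntheticConfig(n_trials=1, n_otus=120, seed=3)
    return generate_trial(cfg, 0)


def make_meta(n_per_cell=2, trial_id="T01", biomass=None):
    meta = []
    k = 0
    for tr in ("ragweed", "sunflower"):
        for fi in ("ragweed", "sunflower"):
            for _ in range(n_per_cell):
                b = 1.0 + k if biomass is None else biomass[k]
                meta.append(PotMetadata(f"p{k:02d}", trial_id, tr, fi, b))
                k += 1
    return meta
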