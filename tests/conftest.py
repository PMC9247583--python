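import numpy as np
import pandas as pd
import pytest

from soilsucc.io import OtuTable
from soilsucc.synth import DomainSpec, Scenario, generate_community


def make_metadata(n_plots=4, shape=(5, 5), stages=None):
    stages = stages or [f"stage{k}" for k in range(n_plots)]
    rows = []
    for k in range(n_plots):
        for r in range(shape[0]):
            for c in range(shape[1]):
                rows.append({"sample_id": f"P{k}_r{r}c{c}", "plot_id": f"P{k}",
                             "row": r, "col": c, "stage": stages[k]})
    return pd.DataFrame(rows)


def random_table(rng, n_samples=10, n_otus=20, domain="bacteria"):
    counts = rng.integers(0, 50, size=(n_samples, n_otus))
    counts[:, 0] += 1  # guarantee nonzero row sums
    return OtuTable([f"s{i}" for i in range(n_samples)],
                    [f"otu{j:03d}" for j in range(n_otus)], counts, domain)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def metadata_4x25():
    return make_metadata()


@pytest.fixture(scope="session")
def small_community():
    """One moderately specialised domain on the default 10x10 design."""
    scen = Scenario(domains=(DomainSpec("bacteria", 120, 0.5, 6.0),),
                    env_effects={})
    return generate_community(scen, seed=7)


@pytest.fixture(scope="session")
def env_community():
    """Community with habitat preference and pH/elevation-driven composition."""
    scen = Scenario(domains=(DomainSpec("bacteria", 150, 0.3, 3.0),))
    return generate_community(scen, seed=11)
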