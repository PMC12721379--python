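import numpy as np
import pandas as pd
import pytest

from mucinet.simulate import GeneratorConfig, simulate_community
from mucinet.tables import load_ec_catalog

#: canonical packaged fixture settings; the golden files under tests/data
#: were produced from exactly this config
FIXTURE_CONFIG = dict(
    n_samples=12,
    n_species=20,
    n_clusters=4,
    n_competitive=5,
    n_opportunistic=4,
    total_reads_per_sample=20000,
    seed=20240901,
)


@pytest.fixture(scope="session")
def catalog():
    return load_ec_catalog()


@pytest.fixture(scope="session")
def fixture_config():
    return GeneratorConfig(**FIXTURE_CONFIG)


@pytest.fixture(scope="session")
def fixture_community(fixture_config):
    return simulate_community(fixture_config)


@pytest.fixture(scope="session")
def default_community():
    """One full-size default community shared by the recovery tests."""
    return simulate_community(GeneratorConfig(seed=7))


def make_stratified(records, samples=None, totals=None):
    """Small StratifiedFunctionTable from (sample, ec, species, cpm) tuples."""
    from mucinet.tables import StratifiedFunctionTable

    strata = pd.DataFrame(records, columns=["sample", "ec", "species", "cpm"])
    if samples is None:
        samples = sorted(strata["sample"].unique())
    ecs = sorted(strata["ec"].unique())
    tot = pd.DataFrame(0.0, index=samples, columns=ecs)
    sums = strata.groupby(["sample", "ec"])["cpm"].sum()
    for (sample, ec), v in sums.items():
        tot.at[sample, ec] = v
    if totals:
        for (sample, ec), v in totals.items():
            tot.at[sample, ec] = v
    return StratifiedFunctionTable(strata, tot)
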