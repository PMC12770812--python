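import numpy as np
import pytest

from piedfly import ingest, inference, synthetic


def small_config(**over):
    """A reduced two-site configuration for fast tests."""
    defaults = dict(n_years=8, start_year=2001)
    defaults.update(over)
    return synthetic.SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def truth_small():
    return synthetic.make_truth(small_config(), seed=7)


@pytest.fixture(scope="session")
def dataset_small(truth_small):
    return synthetic.simulate_dataset(truth_small, seed=8)


def as_ipm_data(ds) -> ingest.IPMData:
    return ingest.IPMData(
        marrays=ingest.build_marrays(ds.captures),
        nests=ds.nests,
        counts=ds.counts,
        covariates={k: v.values for k, v in ds.covariates.items()},
    )


@pytest.fixture(scope="session")
def data_small(dataset_small):
    return as_ipm_data(dataset_small)


@pytest.fixture(scope="session")
def draws_small(data_small):
    """A short but real posterior fit on the small dataset, shared by tests."""
    cfg = inference.MCMCConfig(chains=2, iterations=600, burn_in=200, thin=2)
    return inference.fit(inference.ModelSpec(), data_small, cfg, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
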