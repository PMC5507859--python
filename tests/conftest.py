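import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fryflora as ff
from fryflora.tables import (
    CountTable, filter_otus, filter_samples, pool_replicates, pooled_records,
)

settings.register_profile(
    "fryflora",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fryflora")

#: seed of the stock scenario used by the deterministic end-to-end checks
SCENARIO_SEED = 1


@pytest.fixture
def toy_filter_table() -> CountTable:
    """4 OTUs crafted for the 50-read / 2-sample retention rule.

    A: 100 reads in 3 samples (kept); B: 49 reads in 2 samples (too few
    reads); C: 60 reads in 1 sample (too few samples); D: 200 reads in 3
    samples (kept).
    """
    return CountTable(pd.DataFrame(
        {
            "s1": [40, 25, 60, 70],
            "s2": [30, 24, 0, 60],
            "s3": [30, 0, 0, 70],
        },
        index=["A", "B", "C", "D"],
    ))


@pytest.fixture(scope="session")
def scenario():
    """The stock multi-niche scenario at the fixed test seed."""
    cfg = ff.default_discus_scenario(seed=SCENARIO_SEED)
    return ff.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def pipeline_products(scenario):
    """QC'd counts, pooled metadata and CSS-re-closed proportions."""
    table, records, truth = scenario
    pooled = pool_replicates(table, records)
    qc = filter_otus(filter_samples(pooled, 500))
    pmeta = [r for r in pooled_records(records) if r.sample_id in qc.sample_ids]
    css = ff.css_fit(qc)
    normalized = ff.css_apply(qc, css)
    rel = normalized / normalized.sum(axis=0)
    return qc, pmeta, rel, truth


def random_proportions(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random composition with a sparse support (test helper)."""
    x = rng.dirichlet(np.full(n, 0.5))
    return x / x.sum()
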