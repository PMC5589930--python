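import pandas as pd
import pytest

from tortuga.audit import AuditConfig, BOOKKEEPING_COLUMNS, Dataset
from tortuga.registry import load_registry
from tortuga.synth import SeasonParams, generate_clean_season


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def config():
    return AuditConfig.default()


@pytest.fixture(scope="session")
def clean_season(registry, config):
    """A mid-size clean season shared by injection round-trip tests."""
    params = SeasonParams(
        n_records=200,
        recorders=("Aurora Balam", "Carlos Pech"),
        category_counts={"CRAWL_ANY": 50, "TURTLE_SEEN": 55, "NEST_SEEN": 65,
                         "NEST_MOVED": 10, "NEST_EXCAVATED": 20},
        source_label="clean-200",
        seed=424242,
    )
    return generate_clean_season(params, registry, config)


def make_dataset(rows, source_label="test"):
    """Build a Dataset from a list of cell dicts (missing cells empty)."""
    cols = list(BOOKKEEPING_COLUMNS)
    for r in rows:
        for k in r:
            if k not in cols:
                cols.append(k)
    df = pd.DataFrame([{c: r.get(c, "") for c in cols} for r in rows],
                      columns=cols, dtype="string")
    return Dataset(df=df, source_label=source_label)


@pytest.fixture
def dataset_factory():
    return make_dataset
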