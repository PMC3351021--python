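import numpy as np
import pytest

from ecforest import cascade as cascade_mod
from ecforest import synth
from ecforest.features import extract_table, load_schema, load_tables
from ecforest.records import NON_ENZYME, ECLabel


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture(scope="session")
def strong_dataset():
    """Small strongly separated synthetic dataset shared across tests."""
    spec = synth.separability_preset(
        "strong", n_sub_classes=2, sequences_per_sub_class=25, n_non_enzyme=100, seed=11
    )
    records, comps = synth.generate(spec)
    table = extract_table(records)
    labels = {r.id: r.label for r in records}
    return records, table, labels, comps


@pytest.fixture(scope="session")
def strong_split(strong_dataset):
    records, table, labels, _ = strong_dataset
    enzyme_ids = [r.id for r in records if isinstance(r.label, ECLabel)]
    nonenzyme_ids = [r.id for r in records if r.label == NON_ENZYME]
    train = enzyme_ids[::2]
    test = enzyme_ids[1::2]
    return table, labels, train, test, nonenzyme_ids


@pytest.fixture(scope="session")
def small_params():
    return cascade_mod.ForestParams(ntree=100, mtry=7, seed=0)


@pytest.fixture(scope="session")
def trained_cascade(strong_split, small_params):
    table, labels, train, _, nonenzyme_ids = strong_split
    params = {
        "level1": cascade_mod.ForestParams(100, 25, 0),
        "level2": small_params,
        "level3": small_params,
    }
    return cascade_mod.train_cascade(
        table.loc[train],
        labels,
        table.loc[nonenzyme_ids],
        params_by_level=params,
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length=None):
    residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    if length is None:
        length = int(rng.integers(10, 200))
    return "".join(rng.choice(residues, size=length))
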