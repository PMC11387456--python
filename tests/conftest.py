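import pytest

from siftkit.chemotypes import assign_all
from siftkit.ligand_db import merge_compounds
from siftkit.synthetic_data import SyntheticSpec, simulate_activity_table, simulate_complex


@pytest.fixture(scope="session")
def activity_spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def synthetic_records(activity_spec):
    records, truth = simulate_activity_table(activity_spec)
    return records, truth


@pytest.fixture(scope="session")
def synthetic_entries(synthetic_records):
    records, truth = synthetic_records
    entries, rejects = merge_compounds(records)
    assert not rejects
    assign_all(entries)
    return entries, truth


@pytest.fixture(scope="session")
def ionic_complex():
    return simulate_complex("ionic", seed=7)


@pytest.fixture(scope="session")
def hbond_complex():
    return simulate_complex("hbond", seed=11)
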