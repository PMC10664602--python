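import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from retroval import pseudotime, stratify, synthetic_data

#: small valid/invalid SMILES pools used by fuzzing tests (single fragment,
#: no stereo, so the independent oracle canonicalization route agrees)
VALID_POOL = [
    "CCO", "CCN", "c1ccccc1", "CC(=O)O", "C1CC1", "CCCC", "c1ccncc1",
    "CC(C)O", "CCOC", "CNC", "C#N", "CC(=O)NC", "c1ccc(Cl)cc1", "OCCO",
    "CC(C)(C)C", "CCS", "c1ccc(F)cc1", "CCC(=O)O", "NCCN", "c1ccc(O)cc1",
]
INVALID_POOL = ["not(", "C1CC", "c1ccc1", "X", "C(C)(C)(C)(C)C", "[", ")("]


@pytest.fixture(scope="session")
def public_records():
    spec = synthetic_data.SyntheticProjectSpec(regime="public_like", seed=7)
    return synthetic_data.simulate_project(spec)


@pytest.fixture(scope="session")
def inhouse_records():
    spec = synthetic_data.SyntheticProjectSpec(regime="inhouse_like", seed=7)
    return synthetic_data.simulate_project(spec)


@pytest.fixture(scope="session")
def public_labelled(public_records):
    ptm = pseudotime.pseudo_time_order(public_records)
    return stratify.label_dataset(public_records, pseudo_time_map=ptm)


@pytest.fixture(scope="session")
def inhouse_labelled(inhouse_records):
    ptm = pseudotime.pseudo_time_order(inhouse_records)
    return stratify.label_dataset(inhouse_records, pseudo_time_map=ptm)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return synthetic_data.make_fixture_suite(out, seed=5)
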