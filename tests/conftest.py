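import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mirflow.annotation import derive_clusters, load_packaged_reference
from mirflow.diffexpr import CountMatrix


@pytest.fixture(scope="session")
def reference():
    """Packaged mature + contaminant references."""
    return load_packaged_reference()


@pytest.fixture(scope="session")
def mirnas(reference):
    return reference[0]


@pytest.fixture(scope="session")
def contaminants(reference):
    return reference[1]


@pytest.fixture(scope="session")
def clusters(mirnas):
    return derive_clusters(mirnas)


@pytest.fixture(scope="session")
def seeds_by_name(mirnas):
    return {m.mirna_id: m.seed for m in mirnas}


def make_count_matrix(counts: dict, cell_types: dict) -> CountMatrix:
    """counts: sample_id -> list of ints; cell_types: sample_id -> type."""
    df = pd.DataFrame(counts)
    df.index = [f"mir-{i + 1}" for i in range(len(df))]
    meta = pd.DataFrame(
        {
            "cell_type": pd.Series(cell_types),
            "replicate": {s: i + 1 for i, s in enumerate(cell_types)},
        }
    )
    meta.index.name = "sample_id"
    return CountMatrix(counts=df, sample_meta=meta)
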