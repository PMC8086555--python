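import numpy as np
import pandas as pd
import pytest

from endonet import CommunityParams, OtuTable, PresenceMatrix, generate_community


def make_metadata(sample_ids, organs=None, sites=None):
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "organ": organs or ["bud"] * (n // 2) + ["twig"] * (n - n // 2),
            "site": sites or ["valley"] * n,
            "tree": [f"T{i}" for i in range(n)],
        },
        index=pd.Index(sample_ids, name="sample"),
    )


def make_table(counts, taxon_ids=None, sample_ids=None, organs=None):
    counts = np.asarray(counts)
    taxon_ids = taxon_ids or [f"t{i}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(counts.shape[1])]
    return OtuTable(
        taxon_ids=taxon_ids,
        sample_ids=sample_ids,
        counts=counts,
        metadata=make_metadata(sample_ids, organs=organs),
    )


def make_presence(mat, organs=None):
    mat = np.asarray(mat)
    sample_ids = [f"s{j}" for j in range(mat.shape[1])]
    return PresenceMatrix(
        taxon_ids=[f"t{i}" for i in range(mat.shape[0])],
        sample_ids=sample_ids,
        presence=mat,
        metadata=make_metadata(sample_ids, organs=organs),
    )


@pytest.fixture
def toy_table():
    return make_table([[5, 0, 2], [0, 3, 3], [10, 1, 0]])


@pytest.fixture(scope="session")
def default_community():
    """One study-scale synthetic community shared across read-only tests."""
    table, truth = generate_community(CommunityParams(seed=20210415))
    return table, truth
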