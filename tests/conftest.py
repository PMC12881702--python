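import numpy as np
import pandas as pd
import pytest

from defrac import (AsvTable, SampleRecord, SyntheticCommunityConfig,
                    TaxonomyMap, generate)


def make_table(values, sample_ids=None, asv_ids=None, mode="counts"):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i+1}" for i in range(values.shape[0])]
    asv_ids = asv_ids or [f"asv{j+1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                      columns=asv_ids)
    return AsvTable(df, mode=mode)


def make_record(sample_id, week=1, depth=5.0, fraction="S", dna=1.0):
    return SampleRecord(sample_id=sample_id, week=week, depth=depth,
                        fraction=fraction, dna_concentration=dna)


@pytest.fixture
def tiny_counts():
    return make_table([[3, 1], [0, 4]])


@pytest.fixture
def simple_taxonomy():
    df = pd.DataFrame(
        {
            "domain": "Bacteria",
            "phylum": ["P1", "P1", "P2"],
            "class": ["C1", "C1", "C2"],
            "order": ["O1", "O1", "O2"],
            "family": ["F1", "F1", "F2"],
            "genus": ["GenA", "GenA", "GenB"],
            "community": "prokaryote",
        },
        index=pd.Index(["asv1", "asv2", "asv3"], name="asv_id"),
    )
    return TaxonomyMap(df)


@pytest.fixture(scope="session")
def small_sim():
    """A compact but structured synthetic study shared across test modules."""
    cfg = SyntheticCommunityConfig(
        n_asvs=80, n_weeks=12, depths=(1.0, 10.0, 60.0), bloom_start_week=7,
        phase_split_week=6, seed=42,
    )
    return generate(cfg)
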