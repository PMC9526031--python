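import numpy as np
import pandas as pd
import pytest

from dietbarcoder import (
    ReadTable,
    SimulationConfig,
    gen_read_table,
    gen_seasonal_profiles,
)
from dietbarcoder.model import make_units


def toy_units(n_samples=2, replicates=3, blanks=1, negatives=1):
    rows = []
    for s in range(1, n_samples + 1):
        for r in range(1, replicates + 1):
            rows.append(
                {
                    "unit_id": f"s{s}.r{r}",
                    "sample_id": f"s{s}",
                    "individual_id": f"ind{s}",
                    "group_id": "grpA",
                    "collection_date": "2018-06-01",
                    "replicate_index": r,
                    "unit_type": "sample",
                }
            )
    for b in range(1, blanks + 1):
        rows.append(
            {
                "unit_id": f"blank{b}",
                "sample_id": f"blank{b}",
                "individual_id": "control",
                "group_id": "control",
                "collection_date": "",
                "replicate_index": 1,
                "unit_type": "blank",
            }
        )
    for b in range(1, negatives + 1):
        rows.append(
            {
                "unit_id": f"neg{b}",
                "sample_id": f"neg{b}",
                "individual_id": "control",
                "group_id": "control",
                "collection_date": "",
                "replicate_index": 1,
                "unit_type": "extraction_negative",
            }
        )
    return make_units(rows)


def toy_table(counts, sequences=None, **unit_kw):
    counts = np.asarray(counts)
    units = toy_units(**unit_kw)
    if sequences is None:
        rng = np.random.default_rng(99)
        sequences = [
            "".join(rng.choice(list("ACGT"), size=40)) for _ in range(counts.shape[0])
        ]
    return ReadTable(sequences, counts, units)


@pytest.fixture
def small_cfg():
    return SimulationConfig(n_taxa=8, n_individuals=3, rng_seed=11)


@pytest.fixture
def small_truth(small_cfg):
    return gen_seasonal_profiles(small_cfg)


@pytest.fixture
def small_table(small_cfg, small_truth):
    table, truth = gen_read_table(small_truth, small_cfg)
    return table, truth


def sparse_single_taxon_truth(cfg):
    """Each sample's diet is a single taxon (round-robin), so every sequence
    occupies few units; used by tag-jump recovery experiments."""
    truth = gen_seasonal_profiles(cfg)
    n = cfg.n_taxa
    comps = np.zeros((len(truth.per_sample_composition), n))
    for i in range(comps.shape[0]):
        comps[i, i % n] = 1.0
    truth.per_sample_composition = pd.DataFrame(
        comps,
        index=truth.per_sample_composition.index,
        columns=truth.per_sample_composition.columns,
    )
    return truth
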