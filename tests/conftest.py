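import numpy as np
import pandas as pd
import pytest

import streamfd as sfd


def make_trait_table(profiles, groups):
    """Build a TraitTable from per-taxon profiles and a group layout.

    ``profiles`` maps taxon -> flat list of scores; ``groups`` is a list of
    (group, [modalities]) giving the column structure.
    """
    cols = pd.MultiIndex.from_tuples(
        [(g, m) for g, mods in groups for m in mods]
    )
    df = pd.DataFrame.from_dict(profiles, orient="index")
    df.columns = cols
    return sfd.TraitTable(affinities=df.astype(float))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic paired dataset shared across tests."""
    sc = sfd.SyntheticScenario(
        seed=11, n_pairs=8, pool_size=60, richness_range=(8, 20)
    )
    traits, taxonomy, communities, pairs, truth = sfd.generate(sc)
    return sc, traits, taxonomy, communities, pairs, truth


@pytest.fixture(scope="session")
def tiny_prepared(tiny_dataset):
    _, traits, taxonomy, communities, *_ = tiny_dataset
    filled, merged, mapping, coverage = sfd.prepare(traits, taxonomy, communities)
    space = sfd.build_space(filled)
    return filled, merged, space, mapping, coverage


@pytest.fixture
def toy_traits():
    """Three taxa, two trait groups, hand-set relative frequencies."""
    table = make_trait_table(
        {
            "t1": [1.0, 0.0, 0.0, 1.0, 0.0],
            "t2": [0.0, 1.0, 0.0, 0.5, 0.5],
            "t3": [0.5, 0.5, 0.0, 0.0, 1.0],
        },
        [("g1", ["a", "b", "c"]), ("g2", ["x", "y"])],
    )
    return sfd.normalize_fuzzy(table)
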