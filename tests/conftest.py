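"""Shared fixtures: small catalogs, cohorts and profiles, generated fresh."""

import numpy as np
import pandas as pd
import pytest

from goutmeta.catalog import GeneCatalog
from goutmeta.profiling import ReadMapSample
from goutmeta.synthetic import (
    CohortDesign,
    PlantedEffect,
    generate_catalog,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_catalog():
    catalog, pathways = generate_catalog(
        n_genes=300, n_species=20, n_kos=60, seed=11,
        paralog_family_size={"fraction": 0.15},
    )
    return catalog, pathways


@pytest.fixture(scope="session")
def small_cohort(small_catalog):
    catalog, _ = small_catalog
    design = CohortDesign(
        n_case=12,
        n_control=12,
        planted=[
            PlantedEffect("Species_0001", 2.0, "case"),
            PlantedEffect("Species_0002", 2.0, "control"),
        ],
        depth=8000,
        multiread_rate=0.1,
        seed=7,
    )
    return generate_cohort(catalog, design), design


@pytest.fixture
def toy_catalog():
    """Two genes A (L=100) and B (L=200), the hand-worked redistribution case."""
    table = pd.DataFrame(
        {
            "length": [100, 200],
            "phylum": ["Bacteroidetes", "Firmicutes"],
            "genus": ["GA", "GB"],
            "species": ["SA", "SB"],
            "ko": ["K00001", "K00002"],
            "family_id": ["fam_1", "fam_1"],
        },
        index=pd.Index(["A", "B"], name="gene_id"),
    )
    return GeneCatalog(table=table, paralog_families=[("A", "B")])


def random_readmap(rng: np.random.Generator, gene_ids, sample_id="s1", max_multi=4):
    """A random small read-map sample over the given genes (fuzzing helper)."""
    unique = {
        g: int(rng.integers(0, 30))
        for g in gene_ids
        if rng.random() < 0.8
    }
    multi = []
    for _ in range(int(rng.integers(0, max_multi + 1))):
        size = int(rng.integers(2, min(len(gene_ids), 4) + 1))
        genes = tuple(sorted(rng.choice(gene_ids, size=size, replace=False)))
        multi.append((genes, int(rng.integers(1, 20))))
    return ReadMapSample(sample_id=sample_id, unique_counts=unique, multi_groups=multi)
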