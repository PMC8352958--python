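"""Reference gene catalog: gene lengths, taxonomic lineages and KO assignments.

The catalog is the coordinate system for everything downstream: read-mapping
tables are expressed in its gene ids, gene lengths enter the abundance
calculation, and the lineage / KO columns drive aggregation to phylum, genus,
species and KO profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINEAGE_RANKS = ("phylum", "genus", "species")

CATALOG_COLUMNS = ("length", "phylum", "genus", "species", "ko", "family_id")


@dataclass
class GeneCatalog:
    """Table of genes indexed by gene id.

    ``table`` columns: ``length`` (bp, >= 100), ``phylum``/``genus``/``species``
    (empty string = unassigned at that rank), ``ko`` (empty string = no KO) and
    ``family_id`` (paralog family label, empty string = not in a family).
    ``paralog_families`` lists the gene-id tuples of each multi-species paralog
    family; multi-mapped reads are confined to these sets.
    """

    table: pd.DataFrame
    paralog_families: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in CATALOG_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"catalog table missing columns: {missing}")
        if not self.table.index.is_unique:
            raise ValueError("gene ids must be unique")
        if len(self.table) and (self.table["length"] < 100).any():
            raise ValueError("gene lengths must be >= 100 bp")
        # a species-level call requires genus and phylum; genus requires phylum
        tab = self.table
        if len(tab):
            bad = ((tab["species"] != "") & ((tab["genus"] == "") | (tab["phylum"] == ""))) | (
                (tab["genus"] != "") & (tab["phylum"] == "")
            )
            if bad.any():
                raise ValueError(f"inconsistent lineages for genes: {list(tab.index[bad])[:5]}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def lengths(self) -> pd.Series:
        return self.table["length"]

    def rank_map(self, rank: str) -> pd.Series:
        """gene id -> taxon name at ``rank`` ('phylum'|'genus'|'species'|'ko');
        genes unassigned at that rank are dropped."""
        if rank not in LINEAGE_RANKS and rank != "ko":
            raise ValueError(f"unknown rank: {rank!r}")
        col = self.table[rank]
        return col[col != ""]

    def species_of(self) -> pd.Series:
        return self.table["species"]


def empty_catalog() -> GeneCatalog:
    table = pd.DataFrame(
        {
            "length": pd.Series(dtype=int),
            "phylum": pd.Series(dtype=str),
            "genus": pd.Series(dtype=str),
            "species": pd.Series(dtype=str),
            "ko": pd.Series(dtype=str),
            "family_id": pd.Series(dtype=str),
        },
        index=pd.Index([], name="gene_id", dtype=str),
    )
    return GeneCatalog(table=table)


def families_from_table(table: pd.DataFrame) -> list[tuple[str, ...]]:
    """Reconstruct paralog family tuples from the family_id column."""
    fam = table["family_id"]
    groups = table.index[fam != ""].to_series().groupby(fam[fam != ""]).apply(tuple)
    return [tuple(g) for g in groups.sort_index()]
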