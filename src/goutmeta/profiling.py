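"""Relative-abundance profiles from read-mapping tables.

The central computation redistributes multi-mapped reads across their candidate
genes in proportion to the genes' unique-read abundance, then normalizes to a
per-sample relative-abundance vector:

    Ab(U)_i = U_i / L_i                       (unique part)
    Co_i    = Ab(U)_i / sum_{j in S} Ab(U)_j  (share within candidate set S)
    Ab(M)_i = sum over groups S ∋ i of  c_S * Co_i / L_i
    Ab(G)_i = (Ab(U)_i + Ab(M)_i) / sum_j (Ab(U)_j + Ab(M)_j)

where U_i is the number of reads mapping only to gene i, L_i its length, and
c_S the number of reads whose candidate set is exactly the gene set S.  When
every gene in a candidate set has zero unique abundance the read mass is split
equally among the candidates (conserving reads rather than dropping them).

Also here: taxonomy assignment from homology hit tables, aggregation of gene
profiles to taxon/KO level, prevalence filtering, read downsampling and the
Bacteroidetes/Firmicutes ratio.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import LINEAGE_RANKS, GeneCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "ReadMapSample",
    "AbundanceProfile",
    "HitRecord",
    "gene_abundance",
    "build_gene_profile",
    "downsample",
    "prevalence_filter",
    "assign_taxonomy",
    "aggregate",
    "bf_ratio",
    "filter_function_hits",
]


@dataclass
class ReadMapSample:
    """Per-sample mapping counts over catalog genes.

    ``unique_counts``: gene id -> number of reads mapping to that gene only.
    ``multi_groups``: (gene-id tuple of size >= 2, count) pairs, one per
    distinct candidate set, counting reads that map to exactly that set.
    """

    sample_id: str
    unique_counts: dict[str, int] = field(default_factory=dict)
    multi_groups: list[tuple[tuple[str, ...], int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.unique_counts.values()):
            raise ValueError(f"{self.sample_id}: negative unique count")
        for genes, count in self.multi_groups:
            if len(set(genes)) < 2:
                raise ValueError(f"{self.sample_id}: multi-read group with fewer than 2 genes")
            if count < 0:
                raise ValueError(f"{self.sample_id}: negative multi-read count")

    @property
    def total_reads(self) -> int:
        return int(sum(self.unique_counts.values()) + sum(c for _, c in self.multi_groups))


@dataclass
class AbundanceProfile:
    """Samples x features relative-abundance matrix at one annotation level."""

    data: pd.DataFrame  # rows = samples, columns = features
    level: str  # gene | phylum | genus | species | ko

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def features(self) -> pd.Index:
        return self.data.columns


@dataclass(frozen=True)
class HitRecord:
    """One homology alignment of a catalog gene against a reference sequence."""

    gene_id: str
    phylum: str
    genus: str
    species: str
    identity: float  # percent
    coverage: float  # percent of gene length

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("identity and coverage must be in [0, 100]")


def gene_abundance(
    sample: ReadMapSample, catalog: GeneCatalog
) -> tuple[pd.Series, pd.Series]:
    """Per-gene abundance of one sample.

    Returns ``(raw, relative)``: the unnormalized Ab(U)+Ab(M) vector and the
    normalized Ab(G) vector, both indexed by the full catalog gene list.
    A sample with zero total abundance yields an all-zero relative row (with a
    warning) rather than NaNs.
    """
    gene_ids = catalog.gene_ids
    pos = {g: i for i, g in enumerate(gene_ids)}
    lengths = catalog.lengths.to_numpy(dtype=float)

    unknown = [g for g in sample.unique_counts if g not in pos]
    unknown += [g for genes, _ in sample.multi_groups for g in genes if g not in pos]
    if unknown:
        raise KeyError(f"{sample.sample_id}: gene ids not in catalog: {sorted(set(unknown))[:5]}")

    u = np.zeros(len(gene_ids))
    for g, c in sample.unique_counts.items():
        u[pos[g]] = c
    ab_u = np.divide(u, lengths, out=np.zeros_like(u), where=lengths > 0)

    ab_m = np.zeros_like(ab_u)
    for genes, count in sample.multi_groups:
        if count == 0:
            continue
        idx = np.fromiter((pos[g] for g in genes), dtype=int)
        denom = ab_u[idx].sum()
        if denom > 0:
            co = ab_u[idx] / denom
        else:
            # all candidates unique-silent: split the reads equally to conserve mass
            logger.debug(
                "%s: multi-read group %s has zero unique abundance; splitting equally",
                sample.sample_id,
                genes,
            )
            co = np.full(len(idx), 1.0 / len(idx))
        ab_m[idx] += count * co / lengths[idx]

    raw = ab_u + ab_m
    total = raw.sum()
    if total > 0:
        rel = raw / total
    else:
        warnings.warn(f"{sample.sample_id}: zero total abundance; emitting all-zero row")
        rel = np.zeros_like(raw)
    return (
        pd.Series(raw, index=gene_ids, name=sample.sample_id),
        pd.Series(rel, index=gene_ids, name=sample.sample_id),
    )


def build_gene_profile(samples: list[ReadMapSample], catalog: GeneCatalog) -> AbundanceProfile:
    """Stack per-sample Ab(G) rows into a gene-level profile."""
    rows = [gene_abundance(s, catalog)[1] for s in samples]
    data = pd.DataFrame(rows)
    data.index.name = "sample_id"
    return AbundanceProfile(data=data, level="gene")


def downsample(sample: ReadMapSample, target_reads: int, seed: int) -> ReadMapSample:
    """Subsample the read population to ``target_reads`` without replacement.

    Unique reads and multi-read instances are treated as one population, so
    the subsample is exactly hypergeometric over the count categories.
    """
    total = sample.total_reads
    if target_reads > total:
        raise ValueError(
            f"{sample.sample_id}: target {target_reads} exceeds total mapped reads {total}"
        )
    if target_reads == total:
        return ReadMapSample(
            sample_id=sample.sample_id,
            unique_counts=dict(sample.unique_counts),
            multi_groups=list(sample.multi_groups),
        )
    unique_items = sorted(sample.unique_counts.items())
    counts = [c for _, c in unique_items] + [c for _, c in sample.multi_groups]
    rng = np.random.default_rng(seed)
    kept = rng.multivariate_hypergeometric(np.asarray(counts, dtype=np.int64), target_reads)
    n_u = len(unique_items)
    new_unique = {g: int(k) for (g, _), k in zip(unique_items, kept[:n_u]) if k > 0}
    new_multi = [
        (genes, int(k)) for (genes, _), k in zip(sample.multi_groups, kept[n_u:]) if k > 0
    ]
    return ReadMapSample(sample.sample_id, new_unique, new_multi)


def prevalence_filter(profile: AbundanceProfile, min_fraction: float = 0.10) -> AbundanceProfile:
    """Keep features detected (abundance > 0) in at least
    ``ceil(min_fraction * n_samples)`` samples; retained rows are not
    renormalized."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    n = len(profile.data)
    need = math.ceil(min_fraction * n)
    keep = (profile.data > 0).sum(axis=0) >= need
    return AbundanceProfile(data=profile.data.loc[:, keep], level=profile.level)


# identity thresholds (percent) a hit must *exceed* for its taxon to vote at a rank
RANK_IDENTITY_THRESHOLDS = {"phylum": 65.0, "genus": 85.0, "species": 95.0}
MIN_COVERAGE = 70.0
MIN_IDENTITY = 65.0


def _consensus(names: list[str]) -> str:
    """Taxon named by >= 50% of voting hits; an exact tie at the top is no
    consensus and yields unassigned."""
    votes = Counter(n for n in names if n)
    if not votes:
        return ""
    ranked = votes.most_common()
    top_name, top_count = ranked[0]
    if top_count / sum(votes.values()) < 0.5:
        return ""
    if len(ranked) > 1 and ranked[1][1] == top_count:
        return ""
    return top_name


def assign_taxonomy(hits: list[HitRecord]) -> dict[str, str]:
    """Lineage call for one gene from its alignment hits.

    Hits with coverage < 70% or identity < 65% are discarded; at each rank only
    hits whose identity exceeds the rank threshold (>65 phylum, >85 genus,
    >95 species) vote; the rank is assigned to the taxon with >= 50% consensus
    among voters (unique top).  A rank is blanked whenever its parent rank is
    unassigned, so the emitted lineage is always consistent.
    """
    retained = [h for h in hits if h.coverage >= MIN_COVERAGE and h.identity >= MIN_IDENTITY]
    lineage = {}
    for rank in LINEAGE_RANKS:
        voters = [getattr(h, rank) for h in retained if h.identity > RANK_IDENTITY_THRESHOLDS[rank]]
        lineage[rank] = _consensus(voters)
    if lineage["phylum"] == "":
        lineage["genus"] = ""
    if lineage["genus"] == "":
        lineage["species"] = ""
    return lineage


def aggregate(profile: AbundanceProfile, mapping: pd.Series, level: str) -> AbundanceProfile:
    """Sum member-gene abundances per group (taxon or KO).

    ``mapping``: gene id -> group name, covering a subset of genes; unmapped
    genes contribute to no group, so aggregated row sums are <= 1.
    """
    if profile.level != "gene":
        raise ValueError("aggregate expects a gene-level profile")
    mapping = mapping[mapping != ""].dropna()
    common = profile.data.columns.intersection(mapping.index)
    sub = profile.data.loc[:, common]
    data = sub.T.groupby(mapping.loc[common]).sum().T
    data = data.loc[:, sorted(data.columns)]
    data.index.name = "sample_id"
    return AbundanceProfile(data=data, level=level)


def bf_ratio(
    phylum_profile: AbundanceProfile,
    bacteroidetes: str = "Bacteroidetes",
    firmicutes: str = "Firmicutes",
) -> pd.Series:
    """Per-sample Bacteroidetes/Firmicutes ratio.

    A zero Firmicutes abundance yields +inf for that sample; callers should
    drop non-finite entries before rank tests.
    """
    for name in (bacteroidetes, firmicutes):
        if name not in phylum_profile.data.columns:
            raise KeyError(f"phylum feature absent from profile: {name!r}")
    b = phylum_profile.data[bacteroidetes]
    f = phylum_profile.data[firmicutes]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = b / f
    ratio = ratio.where(f > 0, np.inf)
    n_inf = int(np.isinf(ratio).sum())
    if n_inf:
        logger.warning("bf_ratio: %d sample(s) with zero Firmicutes flagged as +inf", n_inf)
    return ratio.rename("bf_ratio")


def filter_function_hits(
    hits: pd.DataFrame,
    max_evalue: float = 1e-5,
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
) -> pd.Series:
    """Best-hit gene -> enzyme map from a homology hit table.

    ``hits`` columns: gene, enzyme, evalue, identity, coverage.  Hits must have
    e-value < 1e-5, identity > 70% and coverage > 70%; per gene the hit with
    the lowest e-value wins (ties broken by higher identity).
    """
    ok = (
        (hits["evalue"] < max_evalue)
        & (hits["identity"] > min_identity)
        & (hits["coverage"] > min_coverage)
    )
    passing = hits[ok].sort_values(["evalue", "identity"], ascending=[True, False])
    best = passing.drop_duplicates(subset="gene", keep="first")
    return best.set_index("gene")["enzyme"]
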