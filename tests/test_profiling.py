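"""Unit and property tests for the abundance-profiling engine."""

import numpy as np
import pandas as pd
import pytest

from goutmeta.catalog import GeneCatalog
from goutmeta.profiling import (
    AbundanceProfile,
    HitRecord,
    ReadMapSample,
    aggregate,
    assign_taxonomy,
    bf_ratio,
    build_gene_profile,
    downsample,
    filter_function_hits,
    gene_abundance,
    prevalence_filter,
)

from conftest import random_readmap


def per_read_oracle(sample: ReadMapSample, catalog: GeneCatalog) -> np.ndarray:
    """Brute-force redistribution: every multi-mapped read split one at a time
    by the unique-abundance shares of its candidate genes."""
    gene_ids = list(catalog.gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    L = catalog.lengths.to_numpy(dtype=float)
    ab_u = np.zeros(len(gene_ids))
    for g, c in sample.unique_counts.items():
        ab_u[pos[g]] = c / L[pos[g]]
    ab_m = np.zeros_like(ab_u)
    for genes, count in sample.multi_groups:
        idx = [pos[g] for g in genes]
        for _ in range(count):
            s = sum(ab_u[i] for i in idx)
            for i in idx:
                share = ab_u[i] / s if s > 0 else 1.0 / len(idx)
                ab_m[i] += share / L[i]
    raw = ab_u + ab_m
    total = raw.sum()
    return raw / total if total > 0 else raw


class TestGeneAbundance:
    def test_hand_worked_redistribution(self, toy_catalog):
        """A(L=100,U=10), B(L=200,U=40), one shared read -> 31/92 and 61/92."""
        sample = ReadMapSample("s", {"A": 10, "B": 40}, [(("A", "B"), 1)])
        _, rel = gene_abundance(sample, toy_catalog)
        assert rel["A"] == pytest.approx(31 / 92, abs=1e-12)
        assert rel["B"] == pytest.approx(61 / 92, abs=1e-12)

    def test_no_multireads_is_length_normalized_ratio(self, toy_catalog):
        sample = ReadMapSample("s", {"A": 10, "B": 40}, [])
        _, rel = gene_abundance(sample, toy_catalog)
        expect = np.array([10 / 100, 40 / 200])
        expect = expect / expect.sum()
        np.testing.assert_allclose(rel.to_numpy(), expect, atol=1e-15)

    def test_zero_unique_group_splits_equally(self, toy_catalog):
        sample = ReadMapSample("s", {}, [(("A", "B"), 6)])
        raw, rel = gene_abundance(sample, toy_catalog)
        # 3 reads' worth each: A gets 3/100, B gets 3/200
        assert raw["A"] == pytest.approx(3 / 100)
        assert raw["B"] == pytest.approx(3 / 200)
        assert rel.sum() == pytest.approx(1.0)

    def test_matches_per_read_oracle_on_fuzzed_samples(self, small_catalog):
        catalog, _ = small_catalog
        sub = GeneCatalog(table=catalog.table.iloc[:20].copy())
        genes = list(sub.gene_ids)
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(100):
            sample = random_readmap(rng, genes)
            if sample.total_reads == 0:
                continue
            _, rel = gene_abundance(sample, sub)
            np.testing.assert_allclose(
                rel.to_numpy(), per_read_oracle(sample, sub), atol=1e-12
            )
            checked += 1
        assert checked >= 90

    def test_row_sums_to_one_and_scale_invariance(self, small_catalog):
        catalog, _ = small_catalog
        genes = list(catalog.gene_ids[:15])
        sub = GeneCatalog(table=catalog.table.loc[genes].copy())
        rng = np.random.default_rng(1)
        sample = random_readmap(rng, genes)
        _, rel = gene_abundance(sample, sub)
        assert rel.sum() == pytest.approx(1.0, abs=1e-9)
        scaled = ReadMapSample(
            "s", {g: 7 * c for g, c in sample.unique_counts.items()},
            [(gs, 7 * c) for gs, c in sample.multi_groups],
        )
        _, rel7 = gene_abundance(scaled, sub)
        np.testing.assert_allclose(rel.to_numpy(), rel7.to_numpy(), atol=1e-12)

    def test_unknown_gene_and_zero_sample(self, toy_catalog):
        with pytest.raises(KeyError):
            gene_abundance(ReadMapSample("s", {"Z": 1}, []), toy_catalog)
        with pytest.warns(UserWarning, match="zero total"):
            _, rel = gene_abundance(ReadMapSample("s", {}, []), toy_catalog)
        assert (rel == 0).all()


class TestDownsample:
    def test_identity_and_empty(self, toy_catalog):
        sample = ReadMapSample("s", {"A": 5, "B": 3}, [(("A", "B"), 2)])
        same = downsample(sample, 10, seed=0)
        assert same.unique_counts == sample.unique_counts
        assert same.multi_groups == sample.multi_groups
        empty = downsample(sample, 0, seed=0)
        assert empty.total_reads == 0

    def test_target_above_total_raises(self):
        sample = ReadMapSample("s", {"A": 5}, [])
        with pytest.raises(ValueError, match="s"):
            downsample(sample, 6, seed=0)

    def test_half_depth_retention_frequency(self):
        """Hypergeometric: each read kept with frequency 1/2 +- 3 s.e."""
        sample = ReadMapSample("s", {"A": 100, "B": 100}, [(("A", "B"), 100)])
        reps = 300
        kept_a = np.array(
            [downsample(sample, 150, seed=i).unique_counts.get("A", 0) for i in range(reps)]
        )
        frac = kept_a.mean() / 100
        se = np.sqrt(0.25 / 100 / reps) * 3  # binomial-scale bound
        assert abs(frac - 0.5) < max(3 * se, 0.02)

    def test_conservation(self):
        sample = ReadMapSample("s", {"A": 40, "B": 25}, [(("A", "B"), 35)])
        for target in (1, 17, 99):
            assert downsample(sample, target, seed=3).total_reads == target


class TestPrevalenceFilter:
    def test_threshold_arithmetic(self):
        data = pd.DataFrame(np.zeros((20, 3)), columns=["ubiq", "rare", "two"])
        data["ubiq"] = 0.1
        data.loc[data.index[0], "rare"] = 0.2
        data.loc[data.index[:2], "two"] = 0.2
        prof = AbundanceProfile(data=data, level="gene")
        kept = prevalence_filter(prof, 0.10).data.columns
        # need >= ceil(0.1*20) = 2 detections
        assert "ubiq" in kept and "two" in kept and "rare" not in kept

    def test_full_prevalence_only_ubiquitous(self):
        data = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 0.0]})
        kept = prevalence_filter(AbundanceProfile(data, "gene"), 1.0).data.columns
        assert list(kept) == ["a"]

    def test_no_renormalization(self):
        data = pd.DataFrame({"a": [0.6, 0.6], "b": [0.4, 0.0]})
        out = prevalence_filter(AbundanceProfile(data, "gene"), 0.9).data
        assert (out["a"] == 0.6).all()


class TestAssignTaxonomy:
    def test_unanimous_hits_assign_full_lineage(self):
        hits = [HitRecord("g", "P", "G", "X", identity=99, coverage=90)] * 3
        lin = assign_taxonomy(hits)
        assert lin == {"phylum": "P", "genus": "G", "species": "X"}

    def test_even_species_tie_is_unassigned(self):
        hits = [
            HitRecord("g", "P", "G", "X", 99, 90),
            HitRecord("g", "P", "G", "X", 99, 90),
            HitRecord("g", "P", "G", "Y", 99, 90),
            HitRecord("g", "P", "G", "Y", 99, 90),
        ]
        lin = assign_taxonomy(hits)
        assert lin["species"] == ""
        assert lin["genus"] == "G"

    def test_rank_identity_thresholds(self):
        """identity 90 votes at genus (>85) but not species (needs >95)."""
        hits = [HitRecord("g", "P", "G", "X", identity=90, coverage=90)] * 2
        lin = assign_taxonomy(hits)
        assert lin["genus"] == "G" and lin["species"] == ""

    def test_coverage_and_identity_retention(self):
        low_cov = [HitRecord("g", "P", "G", "X", 99, 50)]
        assert assign_taxonomy(low_cov) == {"phylum": "", "genus": "", "species": ""}
        assert assign_taxonomy([]) == {"phylum": "", "genus": "", "species": ""}

    def test_child_blanked_without_parent(self):
        # species voters agree on X but phylum voters tie -> whole lineage blank
        hits = [
            HitRecord("g", "P1", "G", "X", 99, 90),
            HitRecord("g", "P2", "G", "X", 99, 90),
        ]
        lin = assign_taxonomy(hits)
        assert lin == {"phylum": "", "genus": "", "species": ""}


class TestAggregate:
    def test_species_sums_and_unannotated_remainder(self, small_cohort, small_catalog):
        catalog, _ = small_catalog
        cohort, _ = small_cohort
        gp = build_gene_profile(cohort.samples[:4], catalog)
        sp = aggregate(gp, catalog.rank_map("species"), "species")
        # aggregation never increases mass
        assert (sp.data.sum(axis=1) <= 1 + 1e-9).all()
        # manual check on one sample and one species
        s0 = gp.data.iloc[0]
        target = catalog.table.index[catalog.table["species"] == "Species_0001"]
        assert sp.data.iloc[0]["Species_0001"] == pytest.approx(s0.loc[target].sum())

    def test_ko_aggregation_conserves_annotated_mass(self, small_cohort, small_catalog):
        catalog, _ = small_catalog
        cohort, _ = small_cohort
        gp = build_gene_profile(cohort.samples[:3], catalog)
        ko = aggregate(gp, catalog.rank_map("ko"), "ko")
        annotated = catalog.table.index[catalog.table["ko"] != ""]
        expected = gp.data.loc[:, gp.data.columns.intersection(annotated)].sum(axis=1)
        np.testing.assert_allclose(ko.data.sum(axis=1), expected, atol=1e-12)

    def test_single_species_aggregates_to_one(self, toy_catalog):
        data = pd.DataFrame({"A": [0.3], "B": [0.7]}, index=["s"])
        one = aggregate(
            AbundanceProfile(data, "gene"),
            pd.Series({"A": "S", "B": "S"}),
            "species",
        )
        assert one.data.iloc[0]["S"] == pytest.approx(1.0)


class TestBfRatio:
    def test_arithmetic_and_flagging(self):
        data = pd.DataFrame(
            {"Bacteroidetes": [0.2, 0.4, 0.3], "Firmicutes": [0.2, 0.2, 0.0]},
            index=["s1", "s2", "s3"],
        )
        r = bf_ratio(AbundanceProfile(data, "phylum"))
        assert r["s1"] == pytest.approx(1.0)
        assert r["s2"] == pytest.approx(2.0)
        assert np.isinf(r["s3"])

    def test_absent_phylum_raises(self):
        data = pd.DataFrame({"Bacteroidetes": [0.2]}, index=["s"])
        with pytest.raises(KeyError):
            bf_ratio(AbundanceProfile(data, "phylum"))


class TestFilterFunctionHits:
    def test_thresholds_and_best_hit(self):
        hits = pd.DataFrame(
            {
                "gene": ["g1", "g1", "g2", "g3", "g4", "g5"],
                "enzyme": ["e1", "e2", "e3", "e4", "e5", "e6"],
                "evalue": [1e-10, 1e-8, 1e-4, 1e-9, 1e-6, 1e-7],
                "identity": [90, 95, 90, 60, 80, 75],
                "coverage": [90, 90, 90, 90, 65, 80],
            }
        )
        kept = filter_function_hits(hits)
        # g1 best hit by lowest e-value; g2 fails e-value; g3 identity; g4 coverage
        assert kept.to_dict() == {"g1": "e1", "g5": "e6"}
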