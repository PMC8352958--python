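"""Tests for richness, diversity, ordination, PERMANOVA and enterotyping."""

import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import permanova as skbio_permanova
from sklearn.metrics import adjusted_rand_score

from goutmeta import diversity as dv
from goutmeta.synthetic import generate_community_types


def incidence_with(det_counts, n_samples):
    """Incidence matrix where feature j is detected in det_counts[j] samples."""
    inc = np.zeros((n_samples, len(det_counts)))
    for j, c in enumerate(det_counts):
        inc[:c, j] = 1
    return inc


class TestChao2:
    def test_closed_form_bias_corrected(self):
        # S_obs=10, q1=4, q2=2 -> 10 + 4*3/(2*3) = 12
        inc = incidence_with([1, 1, 1, 1, 2, 2, 3, 3, 4, 5], 5)
        assert dv.chao2(inc) == pytest.approx(12.0)

    def test_no_singletons_returns_observed(self):
        inc = incidence_with([2, 3, 4, 2], 4)
        assert dv.chao2(inc) == pytest.approx(4.0)

    def test_all_ubiquitous(self):
        inc = np.ones((3, 7))
        assert dv.chao2(inc) == pytest.approx(7.0)

    def test_classic_flavor(self):
        inc = incidence_with([1, 1, 1, 1, 2, 2, 3, 3, 4, 5], 5)
        assert dv.chao2(inc, bias_corrected=False) == pytest.approx(10 + 16 / 4)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            dv.chao2(np.ones((1, 5)))

    def test_estimate_at_least_observed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            inc = rng.random((6, 30)) < 0.3
            s_obs = (inc.sum(axis=0) > 0).sum()
            assert dv.chao2(inc) >= s_obs


class TestRarefaction:
    def test_deterministic_and_flat_for_ubiquitous(self):
        inc = np.ones((6, 9))
        c1 = dv.rarefaction_curve(inc, n_resamples=20, seed=1)
        c2 = dv.rarefaction_curve(inc, n_resamples=20, seed=1)
        pd.testing.assert_frame_equal(c1, c2)
        assert (c1["mean_richness"] == 9).all()

    def test_curve_settles_nondecreasing_past_transient(self):
        """Beyond the small-k transient (where the bias-corrected Chao2
        correction term overshoots because q2 ~ 0) the mean curve is
        nondecreasing within Monte-Carlo noise, across seeds."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            inc = rng.random((12, 200)) < 0.2
            curve = dv.rarefaction_curve(inc, n_resamples=60, seed=seed + 100)
            tail = curve[curve["k"] >= 6].reset_index(drop=True)
            diffs = np.diff(tail["mean_richness"])
            noise = 3 * tail["sd"].max() / np.sqrt(60)
            assert (diffs > -noise).all()


class TestAlpha:
    def test_gene_count(self):
        assert dv.gene_count([0, 0, 0]) == 0
        assert dv.gene_count([0, 1.5, 0]) == 1
        assert dv.gene_count([1, 2, 3, 4, 5, 6, 7]) == 7

    def test_shannon_closed_forms(self):
        assert dv.shannon(np.ones(8) / 8) == pytest.approx(np.log(8))
        assert dv.shannon([1.0]) == 0.0
        assert dv.shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5 * np.log(2))
        with pytest.raises(ValueError):
            dv.shannon([-0.1, 1.1])

    def test_shannon_maximal_at_uniform(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.dirichlet(np.ones(6))
            assert dv.shannon(p) <= np.log(6) + 1e-12


class TestBrayCurtis:
    def test_closed_forms(self):
        prof = pd.DataFrame(
            [[0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]],
            index=["a", "b", "c", "d"],
        )
        dm = dv.bray_curtis(prof)
        assert dm["a", "b"] == pytest.approx(0.5)
        assert dm["a", "c"] == pytest.approx(0.0)
        assert dm["a", "d"] == pytest.approx(1.0)  # disjoint supports
        assert (dm.data >= 0).all() and (dm.data <= 1 + 1e-12).all()

    def test_all_zero_rows_raise(self):
        prof = pd.DataFrame([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            dv.bray_curtis(prof)


class TestOrdinate:
    def test_duplicated_samples_coincide_and_variance_ordered(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 5))
        x[3] = x[0]
        prof = pd.DataFrame(x)
        coords, ev = dv.ordinate(profile=prof, method="PCA")
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[3], atol=1e-10)
        assert (np.diff(ev) <= 1e-12).all()

    def test_planted_clusters_separate_on_first_axis(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, size=(15, 4))
        b = rng.normal(3, 0.1, size=(15, 4))
        prof = pd.DataFrame(np.vstack([a, b]))
        coords, _ = dv.ordinate(profile=prof, method="PCA")
        lab = np.r_[np.zeros(15), np.ones(15)]
        r = np.corrcoef(coords["PC1"], lab)[0, 1]
        assert abs(r) > 0.9

    def test_pcoa_on_distance(self):
        prof = pd.DataFrame(np.random.default_rng(2).dirichlet(np.ones(5), size=8))
        dm = dv.bray_curtis(prof)
        coords, ev = dv.ordinate(dm=dm, method="PCoA")
        assert coords.shape[0] == 8
        assert ev[0] >= ev[1]


class TestPermanova:
    @pytest.fixture(scope="class")
    @staticmethod
    def null_dm():
        rng = np.random.default_rng(7)
        prof = pd.DataFrame(rng.dirichlet(np.ones(10), size=24))
        return dv.bray_curtis(prof)

    def test_matches_skbio_pseudo_f(self, null_dm):
        """Independent oracle: the categorical pseudo-F equals skbio's."""
        lab = np.array(["a"] * 12 + ["b"] * 12)
        mine = dv.permanova(null_dm, lab, n_perm=99, seed=0)
        ref = skbio_permanova(null_dm, grouping=lab, permutations=0)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_planted_separation_significant(self):
        rng = np.random.default_rng(3)
        a = rng.dirichlet([8, 1, 1, 1], size=15)
        b = rng.dirichlet([1, 1, 1, 8], size=15)
        dm = dv.bray_curtis(pd.DataFrame(np.vstack([a, b])))
        lab = np.array(["a"] * 15 + ["b"] * 15)
        res = dv.permanova(dm, lab, n_perm=999, seed=1)
        assert res.p_value <= 0.001 + 1e-9
        assert res.r2 > 0.3

    def test_r2_invariant_to_within_group_relabeling(self, null_dm):
        lab = np.array(["a"] * 12 + ["b"] * 12)
        r1 = dv.permanova(null_dm, lab, n_perm=9, seed=0).r2
        perm = np.r_[np.random.default_rng(1).permutation(12), 12 + np.arange(12)]
        d2 = null_dm.data[np.ix_(perm, perm)]
        r2 = dv.permanova(d2, lab, n_perm=9, seed=0).r2
        assert r1 == pytest.approx(r2, rel=1e-10)

    def test_continuous_covariate_and_errors(self, null_dm):
        cov = np.linspace(0, 1, 24)
        res = dv.permanova(null_dm, cov, n_perm=99, seed=0)
        assert 0 < res.p_value <= 1 and np.isfinite(res.pseudo_f)
        with pytest.raises(ValueError, match="constant"):
            dv.permanova(null_dm, np.ones(24), n_perm=9, seed=0)

    def test_p_bounds_and_determinism(self, null_dm):
        lab = np.array(["a"] * 12 + ["b"] * 12)
        r1 = dv.permanova(null_dm, lab, n_perm=199, seed=5)
        r2 = dv.permanova(null_dm, lab, n_perm=199, seed=5)
        assert r1.p_value == r2.p_value
        assert 1 / 200 <= r1.p_value <= 1


class TestEnterotype:
    def test_planted_two_types_recovered(self):
        recovered = []
        for seed in range(3):
            prof, truth = generate_community_types(36, n_types=2, seed=seed)
            ent = dv.enterotype(prof, seed=0)
            recovered.append((ent.k, adjusted_rand_score(truth, ent.labels)))
        assert all(k == 2 for k, _ in recovered)
        assert np.mean([ari for _, ari in recovered]) >= 0.9

    def test_k_one_never_considered_and_determinism(self):
        prof, _ = generate_community_types(20, n_types=2, seed=1)
        ent1 = dv.enterotype(prof, k_range=range(2, 4), seed=3)
        ent2 = dv.enterotype(prof, k_range=range(2, 4), seed=3)
        assert 1 not in ent1.ch_scores
        assert (ent1.medoids == ent2.medoids).all()

    def test_identical_samples_raise(self):
        prof = pd.DataFrame(np.tile([0.5, 0.5], (8, 1)))
        with pytest.raises(ValueError):
            dv.enterotype(prof, k_range=range(2, 4))

    def test_pam_is_valid_partition(self):
        rng = np.random.default_rng(0)
        x = rng.random((15, 3))
        d = np.abs(x[:, None] - x[None, :]).sum(-1)
        labels, medoids = dv.pam(d, 3, seed=0)
        assert len(medoids) == 3
        assert set(labels) <= {0, 1, 2}
        # each sample is assigned to its nearest medoid
        assert (d[np.arange(15), medoids[labels]] == d[:, medoids].min(axis=1)).all()


class TestGroupDistances:
    def test_identical_points_give_p_one(self):
        prof = pd.DataFrame(np.tile([0.3, 0.7], (6, 1)), index=list("abcdef"))
        dm = dv.bray_curtis(prof + 0)  # identical rows -> zero distances
        labels = pd.Series(["x", "x", "x", "y", "y", "y"], index=prof.index)
        res = dv.group_distance_comparison(dm, labels)
        assert res.p_value == 1.0
        assert res.mean_within == 0 and res.mean_between == 0

    def test_planted_separation_between_exceeds_within(self):
        rng = np.random.default_rng(2)
        a = rng.dirichlet([20, 1, 1], size=10)
        b = rng.dirichlet([1, 1, 20], size=10)
        prof = pd.DataFrame(np.vstack([a, b]))
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=prof.index)
        res = dv.group_distance_comparison(dv.bray_curtis(prof), labels)
        assert res.mean_between > res.mean_within
        assert res.p_value < 0.01

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.dirichlet(np.ones(4), size=12))
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=prof.index)
        dm = dv.bray_curtis(prof)
        r1 = dv.group_distance_comparison(dm, labels)
        r2 = dv.group_distance_comparison(dm, labels.map({"a": "b", "b": "a"}))
        assert r1.p_value == r2.p_value
        assert r1.mean_between == r2.mean_between

    def test_longitudinal_distances_from_baseline(self):
        rng = np.random.default_rng(5)
        prof = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=9),
            index=[f"s{i}" for i in range(9)],
        )
        dm = dv.bray_curtis(prof)
        out = dv.distances_from_baseline(
            dm, baseline_ids=["s0", "s1", "s2"],
            timepoint_ids={"2W": ["s3", "s4"], "4W": ["s5"]},
        )
        assert out["2W"].shape == (6,)
        assert out["4W"].shape == (3,)
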